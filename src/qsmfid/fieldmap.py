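"""Total-field estimation from complex multi-echo GRE data.

Stage one of the detection chain: a per-voxel nonlinear fit of the
mono-exponential complex signal model

    s_j = A * exp(i*phi0) * exp((i*2*pi*f - R2*) * TE_j)

initialized from temporal phase differences, followed by Laplacian phase
unwrapping of the TE-normalized field phase. The fit operates on complex
data, so spatial phase wrapping does not limit it; with a uniform echo
spacing dTE the model is exactly periodic in f with period 1/dTE, and
fields beyond the temporal Nyquist range alias. Spatial Laplacian
unwrapping of the fitted phase resolves those aliases where the true
field is smooth.
"""

from __future__ import annotations

import numpy as np
import scipy.fft as sfft
from scipy import ndimage

from .core import FieldMap, GridMeta, MultiEchoGRE, wrap_phase

RELIABILITY_FLOOR_FRACTION = 0.05  # of the robust median signal amplitude


# --------------------------------------------------------------------------
# temporal initialization
# --------------------------------------------------------------------------

def temporal_field_init(gre: MultiEchoGRE) -> np.ndarray:
    """Field estimate (ppm) from magnitude-weighted echo-to-echo phase.

    Uses the phase of sum_j s_{j+1} * conj(s_j) divided by 2*pi*dTE for a
    uniform echo spacing; immune to any static phase offset. Aliases for
    |f| above 1/(2*dTE). Falls back to weighted least squares on pairwise
    phase increments when the echo spacing is non-uniform.
    """
    s = gre.data
    dtes = np.diff(gre.tes)
    uniform = np.ptp(dtes) <= 1e-9 * np.mean(dtes)
    if uniform:
        q = np.sum(s[1:] * np.conj(s[:-1]), axis=0)
        f_hz = np.angle(q) / (2.0 * np.pi * dtes[0])
    else:
        theta = np.angle(s[1:] * np.conj(s[:-1]))          # (J-1, ...)
        w = np.abs(s[1:] * np.conj(s[:-1]))
        dt = dtes.reshape(-1, 1, 1, 1)
        num = np.sum(w * theta * dt, axis=0)
        den = np.sum(w * dt * dt, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f_hz = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
        f_hz /= 2.0 * np.pi
    return f_hz / gre.grid.hz_per_ppm


# --------------------------------------------------------------------------
# nonlinear complex fit
# --------------------------------------------------------------------------

def _varpro_amplitude(s, e):
    """Optimal complex amplitude c for model c*e given data s (last axis echoes)."""
    den = np.sum(np.abs(e) ** 2, axis=-1)
    num = np.sum(s * np.conj(e), axis=-1)
    return num / np.maximum(den, 1e-300)


def fit_complex_field(
    gre: MultiEchoGRE,
    init: np.ndarray | None = None,
    max_iter: int = 50,
    rel_tol: float = 1e-6,
    mask: np.ndarray | None = None,
) -> FieldMap:
    """Per-voxel least-squares fit of the complex mono-exponential model.

    A Levenberg-damped Gauss-Newton iteration on (f, R2*) with the complex
    amplitude A*exp(i*phi0) eliminated analytically at each step (variable
    projection), so each voxel solves a 2-parameter problem on the complex
    residual. Voxels whose signal amplitude falls below the reliability
    floor keep the initial field and get reliability 0.

    Parameters
    ----------
    init : ndarray, optional
        Initial field in ppm (e.g. from :func:`temporal_field_init`);
        zeros when omitted.
    mask : ndarray, optional
        Restrict the fit (and the reliability reference statistics) to a
        region, e.g. a body mask; voxels outside keep the initial field
        with reliability 0. Without a mask every voxel with signal is fit.
    """
    grid = gre.grid
    shape = tuple(grid.shape)
    tes = gre.tes
    s_all = gre.data.reshape(gre.n_echoes, -1).T              # (N, J)
    n_vox = s_all.shape[0]

    f_init_hz = (
        np.zeros(shape) if init is None else np.asarray(init) * grid.hz_per_ppm
    ).reshape(-1)

    amp0 = np.abs(s_all).max(axis=1)
    fit_domain = amp0 > 0
    if mask is not None:
        fit_domain &= np.asarray(mask, dtype=bool).reshape(-1)
    active_idx = np.flatnonzero(fit_domain)

    f = f_init_hz.copy()
    # log-magnitude slope as R2* start (clipped to a physical range)
    with np.errstate(divide="ignore", invalid="ignore"):
        lg = np.log(np.maximum(np.abs(s_all[active_idx]), 1e-300))
    r_start = (lg[:, 0] - lg[:, -1]) / (tes[-1] - tes[0])
    r = np.zeros(n_vox)
    r[active_idx] = np.clip(r_start, 0.0, 2000.0)

    s = s_all[active_idx]
    fa = f[active_idx].copy()
    ra = r[active_idx].copy()
    n_act = fa.size
    c = np.zeros(n_act, dtype=np.complex128)
    rss = np.zeros(n_act)
    lam = np.full(n_act, 1e-8)
    live = np.ones(n_act, dtype=bool)

    _, c[:], _, rss[:] = model_parts_sub(s, fa, ra, tes)
    for _ in range(max_iter):
        if not live.any():
            break
        li = np.flatnonzero(live)
        s_l = s[li]
        e_l = np.exp((2j * np.pi * fa[li, None] - ra[li, None]) * tes[None, :])
        c_l = c[li]
        res_l = s_l - c_l[:, None] * e_l
        # Jacobian of the model wrt (f, R): g1 = dmu/df, g2 = dmu/dR
        g1 = c_l[:, None] * (2j * np.pi * tes[None, :]) * e_l
        g2 = -c_l[:, None] * tes[None, :] * e_l
        h11 = np.sum(np.abs(g1) ** 2, axis=1)
        h22 = np.sum(np.abs(g2) ** 2, axis=1)
        h12 = np.sum(np.real(np.conj(g1) * g2), axis=1)
        b1 = np.sum(np.real(np.conj(g1) * res_l), axis=1)
        b2 = np.sum(np.real(np.conj(g2) * res_l), axis=1)

        def solve_step(lam_v, rows=slice(None)):
            d11 = h11[rows] * (1.0 + lam_v)
            d22 = h22[rows] * (1.0 + lam_v)
            det = d11 * d22 - h12[rows] ** 2
            det = np.where(np.abs(det) < 1e-300, 1e-300, det)
            df = (d22 * b1[rows] - h12[rows] * b2[rows]) / det
            dr = (d11 * b2[rows] - h12[rows] * b1[rows]) / det
            return df, dr

        df, dr = solve_step(lam[li])
        f_try = fa[li] + df
        r_try = ra[li] + dr
        _, c_t, _, rss_t = model_parts_sub(s_l, f_try, r_try, tes)
        bad = np.flatnonzero(rss_t > rss[li] * (1.0 + 1e-12))
        # Levenberg damping for the (few) voxels whose plain step failed
        lam_b = lam[li][bad]
        for _damp in range(10):
            if bad.size == 0:
                break
            lam_b = lam_b * 10.0
            df_b, dr_b = solve_step(lam_b, rows=bad)
            f_b = fa[li][bad] + df_b
            r_b = ra[li][bad] + dr_b
            _, c_b, _, rss_b = model_parts_sub(s_l[bad], f_b, r_b, tes)
            ok = rss_b <= rss[li][bad] * (1.0 + 1e-12)
            f_try[bad] = np.where(ok, f_b, f_try[bad])
            r_try[bad] = np.where(ok, r_b, r_try[bad])
            c_t[bad] = np.where(ok, c_b, c_t[bad])
            rss_t[bad] = np.where(ok, rss_b, rss_t[bad])
            df[bad] = np.where(ok, df_b, df[bad])
            dr[bad] = np.where(ok, dr_b, dr[bad])
            lam[li[bad]] = lam_b
            keep = ~ok
            bad = bad[keep]
            lam_b = lam_b[keep]
        accept = rss_t <= rss[li] * (1.0 + 1e-12)
        upd = np.flatnonzero(accept)
        gi = li[upd]
        fa[gi] = f_try[upd]
        ra[gi] = r_try[upd]
        c[gi] = c_t[upd]
        rss[gi] = rss_t[upd]
        lam[li] = np.where(accept, np.maximum(lam[li] * 0.3, 1e-10), lam[li])
        # convergence: relative parameter update below tolerance
        rel_f = np.abs(df) / (np.abs(f_try) + 1.0)
        rel_r = np.abs(dr) / (np.abs(r_try) + 1.0)
        conv = accept & (np.maximum(rel_f, rel_r) < rel_tol)
        live[li[conv]] = False
        live[li[~accept]] &= lam[li][~accept] < 1e8

    # rescue voxels stuck in a wrong local basin: the VARPRO landscape is
    # periodic in f with period 1/dTE, so a coarse f grid over one period
    # followed by a short Gauss-Newton polish finds the global basin
    amp_c = np.abs(c)
    bad = np.flatnonzero((np.sqrt(rss / tes.size) > 0.1 * amp_c) & (amp_c > 0))
    if bad.size:
        period = 1.0 / float(np.mean(np.diff(tes)))
        offsets = (np.arange(16) / 16.0 - 0.5) * period
        best_rss = rss[bad].copy()
        best_f = fa[bad].copy()
        for df0 in offsets:
            _, _, _, rss_t = model_parts_sub(s[bad], fa[bad] + df0, ra[bad], tes)
            better = rss_t < best_rss
            best_f = np.where(better, fa[bad] + df0, best_f)
            best_rss = np.where(better, rss_t, best_rss)
        fb, rb = best_f, ra[bad].copy()
        for _ in range(12):
            ex_b = np.exp((2j * np.pi * fb[:, None] - rb[:, None]) * tes[None, :])
            c_b = _varpro_amplitude(s[bad], ex_b)
            res_b = s[bad] - c_b[:, None] * ex_b
            g1 = c_b[:, None] * (2j * np.pi * tes[None, :]) * ex_b
            g2 = -c_b[:, None] * tes[None, :] * ex_b
            h11 = np.sum(np.abs(g1) ** 2, axis=1) + 1e-300
            h22 = np.sum(np.abs(g2) ** 2, axis=1) + 1e-300
            h12 = np.sum(np.real(np.conj(g1) * g2), axis=1)
            b1 = np.sum(np.real(np.conj(g1) * res_b), axis=1)
            b2 = np.sum(np.real(np.conj(g2) * res_b), axis=1)
            det = np.where(np.abs(h11 * h22 - h12**2) < 1e-300, 1e-300,
                           h11 * h22 - h12**2)
            fb = fb + (h22 * b1 - h12 * b2) / det
            rb = rb + (h11 * b2 - h12 * b1) / det
        _, c_b, _, rss_b = model_parts_sub(s[bad], fb, rb, tes)
        improved = rss_b < rss[bad]
        gi = bad[improved]
        fa[gi] = fb[improved]
        ra[gi] = rb[improved]
        c[gi] = c_b[improved]
        rss[gi] = rss_b[improved]

    f[active_idx] = fa
    r[active_idx] = ra
    amplitude = np.zeros(n_vox)
    phi0 = np.zeros(n_vox)
    residual = np.zeros(n_vox)
    amplitude[active_idx] = np.abs(c)
    phi0[active_idx] = np.angle(c)
    residual[active_idx] = np.sqrt(rss / tes.size)

    # reliability: effective amplitude relative to the robust signal
    # median. The field of a voxel is only constrained if signal
    # persists across at least two echoes, so the model amplitude at the
    # second echo (A * exp(-R2* TE_2)) is the relevant measure: voxels
    # dephased to a single usable echo carry no frequency information.
    te_eff = tes[min(1, tes.size - 1)]
    amp_eff = amplitude * np.exp(-np.clip(r, 0.0, None) * te_eff)
    stat = amp_eff if mask is None else amp_eff[np.asarray(mask).reshape(-1)]
    sig = stat[stat > 0.1 * np.percentile(stat, 99)] if stat.size else stat
    ref = np.median(sig) if sig.size else 0.0
    if ref > 0:
        reliability = np.clip(amp_eff / ref, 0.0, 1.0)
        reliability[amp_eff < RELIABILITY_FLOOR_FRACTION * ref] = 0.0
    else:
        reliability = np.zeros(n_vox)
    # unreliable voxels keep the initial field
    dead = reliability == 0.0
    f[dead] = f_init_hz[dead]

    return FieldMap(
        field_ppm=(f / grid.hz_per_ppm).reshape(shape),
        r2star=r.reshape(shape),
        phi0=phi0.reshape(shape),
        amplitude=amplitude.reshape(shape),
        residual=residual.reshape(shape),
        reliability=reliability.reshape(shape),
        grid=grid,
    )


def model_parts_sub(s, fv, rv, tes):
    ex = np.exp((2j * np.pi * fv[:, None] - rv[:, None]) * tes[None, :])
    den = np.sum(np.abs(ex) ** 2, axis=-1)
    c = np.sum(s * np.conj(ex), axis=-1) / np.maximum(den, 1e-300)
    resid = s - c[:, None] * ex
    rss = np.sum(np.abs(resid) ** 2, axis=1)
    return ex, c, resid, rss


# --------------------------------------------------------------------------
# Laplacian unwrapping
# --------------------------------------------------------------------------

def _laplacian_eigenvalues(shape, voxel_size):
    lams = []
    for n, h in zip(shape, voxel_size):
        k = np.arange(n)
        lams.append((2.0 * np.cos(np.pi * k / n) - 2.0) / (h * h))
    return (
        lams[0][:, None, None] + lams[1][None, :, None] + lams[2][None, None, :]
    )


def _apply_laplacian(vol, lam):
    return sfft.idctn(sfft.dctn(vol, norm="ortho") * lam, norm="ortho")


def laplacian_unwrap(
    wrapped_phase: np.ndarray, grid: GridMeta, congruent: bool = True
) -> np.ndarray:
    """Unwrap phase by solving the Laplacian identity with a Poisson solve.

    Solves lap(phi_u) = cos(phi)*lap(sin phi) - sin(phi)*lap(cos phi)
    where the 7-point discrete Laplacian (voxel-size scaled) is
    diagonalized by a type-II cosine transform — i.e. an FFT of the
    symmetrically extended volume, which imposes reflective boundaries.
    The zero-frequency component is set to 0, so the output equals the
    true phase up to a harmonic/constant component.

    With ``congruent=True`` the Poisson solution only selects the
    per-voxel 2*pi branch and the returned phase is congruent to the
    input (phi + 2*pi*round((phi_u - phi)/2*pi)), which removes the
    smooth approximation error of the Poisson estimate wherever that
    estimate is within pi of the truth.
    """
    phi = np.asarray(wrapped_phase, dtype=np.float64)
    lam = _laplacian_eigenvalues(phi.shape, grid.voxel_size)
    sin, cos = np.sin(phi), np.cos(phi)
    rhs = cos * _apply_laplacian(sin, lam) - sin * _apply_laplacian(cos, lam)
    spec = sfft.dctn(rhs, norm="ortho")
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(lam != 0.0, spec / np.where(lam == 0.0, 1.0, lam), 0.0)
    phi_u = sfft.idctn(inv, norm="ortho")
    if congruent:
        phi_u = phi + 2.0 * np.pi * np.round((phi_u - phi) / (2.0 * np.pi))
    return phi_u


# --------------------------------------------------------------------------
# orchestrated field estimation
# --------------------------------------------------------------------------

def resolve_alias_branches(
    fm: FieldMap,
    tes: np.ndarray,
    min_reliability: float = 0.1,
    smooth_sigma_mm: float = 10.0,
    k_max: int = 3,
):
    """Resolve temporal alias branches using initial-phase consistency.

    With uniform echo spacing dTE the complex signal model is exactly
    degenerate under f -> f + k/dTE together with
    phi0 -> phi0 - 2*pi*k*TE1/dTE. Unless TE1 is a multiple of dTE that
    phase shift is not a multiple of 2*pi, so the fitted phi0 of an
    aliased voxel is displaced from the (spatially smooth) true initial
    phase by a known per-branch offset: selecting the branch k that
    returns phi0 closest to a smoothed phi0 reference de-aliases the
    field without relying on spatial phase continuity of the field
    itself. Modifies `fm` in place; returns ``(fm, resolved)`` where
    `resolved` marks the voxels whose branch was determined.
    """
    tes = np.asarray(tes, dtype=float)
    none = np.zeros(fm.field_ppm.shape, dtype=bool)
    dtes = np.diff(tes)
    if np.ptp(dtes) > 1e-9 * dtes.mean():
        return fm, none  # non-uniform spacing: no exact degeneracy
    dte = float(dtes.mean())
    off = float(wrap_phase(np.array(-2.0 * np.pi * tes[0] / dte)))
    if abs(off) < 0.3:
        return fm, none  # TE1 ~ multiple of dTE: phi0 carries no branch info
    w = np.where(fm.reliability >= min_reliability, fm.reliability, 0.0)
    if not np.any(w > 0):
        return fm, none
    sig_vox = [max(smooth_sigma_mm / v, 1e-6) for v in fm.grid.voxel_size]
    # reliability-weighted smooth reference of the initial phase, built
    # from complex exponentials so reference wrapping is harmless
    num = ndimage.gaussian_filter(w * np.cos(fm.phi0), sig_vox) + 1j * \
        ndimage.gaussian_filter(w * np.sin(fm.phi0), sig_vox)
    den = ndimage.gaussian_filter(w, sig_vox)
    phi_ref = np.angle(np.where(den > 1e-12, num / np.maximum(den, 1e-12), 1.0))
    dphi = wrap_phase(fm.phi0 - phi_ref)
    cands = np.arange(-k_max, k_max + 1)
    trial = np.abs(wrap_phase(dphi[..., None] + cands * off))
    k = cands[np.argmin(trial, axis=-1)]
    k = np.where(w > 0, k, 0)
    fm.field_ppm = fm.field_ppm + k / dte / fm.grid.hz_per_ppm
    fm.phi0 = wrap_phase(fm.phi0 + k * off)
    return fm, w > 0


def estimate_fieldmap(
    gre: MultiEchoGRE,
    mask: np.ndarray | None = None,
    unwrap: bool = True,
) -> FieldMap:
    """Full total-field stage: init, complex fit, de-aliasing, unwrapping.

    With a uniform echo spacing the complex fit is periodic in f with
    period 1/dTE, so the fitted field near strong susceptibility sources
    can alias by integer multiples of 1/dTE. Two complementary
    mechanisms resolve the branch: the initial-phase consistency test
    (:func:`resolve_alias_branches`), which is exact voxel-wise wherever
    the fit is reliable, and Laplacian unwrapping of the TE-normalized
    phase, which handles smooth large-scale wraps: the unwrapped
    surrogate selects the residual integer branch per voxel,
    f -> f + round((f_u - f) * dTE) / dTE, so unaliased voxels keep the
    fitted value exactly.
    """
    init = temporal_field_init(gre)
    fm = fit_complex_field(gre, init=init, mask=mask)
    if not unwrap:
        return fm
    fm, resolved = resolve_alias_branches(fm, gre.tes)
    dte = float(np.mean(np.diff(gre.tes)))
    f_hz = fm.field_ppm * gre.grid.hz_per_ppm
    theta = wrap_phase(2.0 * np.pi * f_hz * dte)
    theta_u = laplacian_unwrap(theta, gre.grid)
    f_u = theta_u / (2.0 * np.pi * dte)
    w = fm.reliability
    wsum = float(w.sum())
    if wsum > 0:
        # restore the mean level the Poisson solve discards
        f_u = f_u + float(np.sum(w * (f_hz - f_u)) / wsum)
    alias = np.round((f_u - f_hz) * dte) / dte
    alias[resolved] = 0.0  # phi0 consistency already fixed those exactly
    fm.field_ppm = (f_hz + alias) / gre.grid.hz_per_ppm
    return fm
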