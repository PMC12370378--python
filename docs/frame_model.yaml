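# Example SBRT-frame rod geometry (institution-specific hardware).
# Reference points are the rod centroids in the frame's own coordinate
# system, in mm; at least three non-collinear points are required.
description: example pelvis SBRT frame, three silicone rods at the base
rod_reference_points:
  - [-60.0, -100.0, 0.0]
  - [0.0, -104.0, 0.0]
  - [60.0, -100.0, 0.0]
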