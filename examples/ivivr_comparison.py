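"""In vitro vs in vivo release comparison (IVIVR) from analytic curves.

Builds corrected-release time courses for a tube experiment and a brain
implantation of the same gel directly from the Fickian slab model (skipping
the imaging steps for speed), interpolates both at shared times, and
tabulates the paired differences. The in vivo-like curve uses a larger
effective diffusivity, reproducing the qualitative finding that release is
faster in brain tissue than in buffer.
"""

import numpy as np

from gelmri import cumulative_release, ivivr_table, simulate_slab_release

t_vitro = np.array([0.0, 24.0, 48.0, 96.0, 144.0])
t_vivo = np.array([0.0, 48.0, 168.0, 336.0, 504.0])

f_vitro = simulate_slab_release(7.0e-11, 5.5e-3, t_vitro * 3600.0)
f_vivo = simulate_slab_release(2.0e-10, 5.5e-3, t_vivo * 3600.0)

vitro = cumulative_release(1 - f_vitro, np.full_like(t_vitro, 40.0), t_vitro,
                           label="in vitro")
vivo = cumulative_release(1 - f_vivo, np.full_like(t_vivo, 5.0), t_vivo,
                          label="in vivo")

table = ivivr_table(vitro, vivo, [48.0, 96.0, 144.0])
print(table.to_string(index=False, float_format=lambda x: f"{x:8.2f}"))
print("\nPositive differences: the same formulation releases its protein")
print("load faster after implantation than in the buffer-release assay.")
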