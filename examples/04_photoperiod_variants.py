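"""Does the nocturnal amplitude gain survive photoperiod changes?

Repeats the nocturnal shared-wiring (config3) comparison under short
(8:16), equinox (12:12) and long (16:8) photoperiods. The sign of the
PA-induced amplitude increase is preserved across all three.
"""

from scn_poincare import (
    PARAM_PRESETS,
    SimulationSettings,
    run_photoperiod_variants,
)
from scn_poincare.core_model import config3

df = run_photoperiod_variants(
    PARAM_PRESETS["set_a"],
    "nocturnal",
    config3(),
    photoperiod_grid=(0.33, 0.5, 0.67),
    K_L=1.0,
    K_PA=-1.0,
    settings=SimulationSettings(seed=1),
)
print(
    df[["photoperiod", "K_PA", "amplitude", "peak_zt",
        "amplitude_increase_pct"]].to_string(index=False)
)
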