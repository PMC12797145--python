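"""Inject a lagged venous confound into a clean volume, then remove it.

The correction extracts the venous reference from the maximum-fBV voxel,
finds the per-voxel lag maximizing |cross-correlation|, and regresses the
lag-shifted reference out of every voxel.
"""

import numpy as np

from eegfmri.correction import correct_volume
from eegfmri.fmri_metrics import compute_rsfa, preprocess_bold
from eegfmri.synth import (SimulationConfig, confound_field,
                           inject_macrovascular_confound, make_atlas,
                           make_neuronal_drivers, make_vessel_model, render_bold)

cfg = SimulationConfig()
atlas = make_atlas(cfg)
vessel = make_vessel_model(cfg)
drivers, _ = make_neuronal_drivers(cfg, participant_seed=10)
clean, _, ref = render_bold(drivers, atlas, cfg, participant_seed=11, vessel=vessel)
injected, amp, lag = inject_macrovascular_confound(clean, vessel, ref, cfg)
corrected, model = correct_volume(injected, max_lag=cfg.max_confound_lag)

peri = (atlas > 0) & (amp > 0.2 * cfg.confound_amplitude)
for name, v in (("clean", clean), ("injected", injected), ("corrected", corrected)):
    rsfa = np.nanmean(compute_rsfa(preprocess_bold(v), mask=peri))
    print(f"perivascular RSFA ({name:9s}): {rsfa:.4f}")
print(f"\nextracted reference vs injected waveform: r = "
      f"{np.corrcoef(model.reference, ref)[0, 1]:.3f}")
print("The confound inflates the fluctuation amplitude of gray matter near")
print("the vessel tree; the lag-optimized nuisance regression restores it.")
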