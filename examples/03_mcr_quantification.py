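"""Quantify relative pesticide content per pixel with MCR-ALS.

Builds a single-pesticide cube at 25 dB SNR, refines the VCA endmembers by
alternating non-negative least squares, and compares the estimated
abundances against the generator's true concentration field.
"""
from serspen.benchmark import mcr_recovery_correlation, noise_sd_for_snr
from serspen.synthetic import ComponentConfig, SceneConfig

comp = ComponentConfig(
    name="chlorpyrifos",
    peaks=((632.0, 14.0, 800.0), (685.0, 14.0, 1000.0), (980.0, 14.0, 550.0),
           (1096.0, 14.0, 450.0), (1240.0, 14.0, 350.0), (1575.0, 14.0, 300.0)),
)
scene = SceneConfig(components=(comp,), n_depth=32, n_lateral=16, seed=7)
sd = noise_sd_for_snr(scene, time_h=24.0, snr_db=25.0)
print(f"noise sigma for a 25 dB cube: {sd:.1f} a.u.")

r = mcr_recovery_correlation(scene, time_h=24.0, snr_db=25.0)
for name, corr in r.items():
    print(f"Pearson r(true concentration, MCR abundance) for {name}: {corr:.4f}")
print("r close to 1 means the factorization recovered the spatial"
      " distribution of the pesticide despite baseline, gain bias and noise.")
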