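#!/usr/bin/env python
"""Design the silent-substitution stimuli on the synthetic device.

Solves the cone-silenced 350%-melanopic background pair and the
melanopsin-silenced +/-5% LMS flicker arms around each background, verifies
the designs by passing them back through the colorimetry, and quantifies
what 8-bit settings quantization would do to the achieved contrasts.

Writes spectra and a design report under results/design/.
"""

from pathlib import Path

import numpy as np

from melflicker.colorimetry import excitation, synthetic_sensitivities, weber_contrast
from melflicker.stimulus_design import solve_background_pair, solve_flicker_modulation
from melflicker.synthetic_data import make_synthetic_device

OUT = Path(__file__).resolve().parent.parent / "results" / "design"
SEED = 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    sens = synthetic_sensitivities()
    device = make_synthetic_device(wavelengths=sens.wavelengths, seed=SEED)
    lines = []

    low, high = solve_background_pair(device, sens, target_mel_contrast=3.5)
    e_lo = excitation(device.spectrum(low), sens)
    e_hi = excitation(device.spectrum(high), sens)
    c = weber_contrast(e_lo, e_hi)
    lines.append("Background pair (silent substitution, melanopsin-directed):")
    lines.append(f"  melanopic Weber contrast: {c['Mel']:.6f} "
                 f"(excitation ratio {e_hi['Mel'] / e_lo['Mel']:.4f}x)")
    for l in ("L", "M", "S"):
        lines.append(f"  residual {l}-cone contrast: {c[l]:.2e}")

    for name, bg in (("low", low), ("high", high)):
        spec = solve_flicker_modulation(device, sens, bg, lms_target=0.05)
        cf = weber_contrast(
            excitation(device.spectrum(bg), sens),
            excitation(device.spectrum(spec.positive_arm_settings), sens),
        )
        lines.append(f"Flicker arms on {name} background:")
        lines.append(
            f"  cone contrasts L/M/S: "
            f"{cf['L']:.6f} / {cf['M']:.6f} / {cf['S']:.6f}; "
            f"melanopsin residual {cf['Mel']:.2e}"
        )
        device.spectrum(bg).to_csv(OUT / f"background_{name}.csv")
        device.spectrum(spec.positive_arm_settings).to_csv(
            OUT / f"flicker_{name}_positive.csv"
        )
        device.spectrum(spec.negative_arm_settings).to_csv(
            OUT / f"flicker_{name}_negative.csv"
        )

    # quantization splatter: what an 8-bit driver would do to the design
    dev8 = make_synthetic_device(
        wavelengths=sens.wavelengths, seed=SEED, quantization_levels=256
    )
    cq = weber_contrast(
        excitation(dev8.spectrum(dev8.quantize(low)), sens),
        excitation(dev8.spectrum(dev8.quantize(high)), sens),
    )
    worst = max(abs(cq[l]) for l in ("L", "M", "S"))
    lines.append("8-bit settings quantization:")
    lines.append(f"  melanopic contrast becomes {cq['Mel']:.4f}")
    lines.append(f"  worst-case cone splatter: {worst:.2e}")

    report = "\n".join(lines) + "\n"
    (OUT / "design_report.txt").write_text(report)
    print(report)


if __name__ == "__main__":
    main()
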