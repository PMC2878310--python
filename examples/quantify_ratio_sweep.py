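"""Recover known light:heavy mixing ratios from synthetic LC-MS pairs.

Mirrors the classic validation design for isotope-label quantification:
peptide pairs are generated at mixing ratios 1:2, 1:1.5, 1:1, 1.5:1 and
2:1 with 5% apex noise, pushed through the full pipeline (spectra ->
XIC -> de-noise -> peak region -> areas -> ratio), and aggregated at
protein level with recursive outlier elimination. For each ratio the
script prints the recovered value and its relative error in percent —
small errors across the whole sweep mean the quantification is accurate
over the usable dynamic range.
"""

import numpy as np
import pandas as pd

from wavequant import SyntheticSpec, generate_spectra, protein_ratio, relative_error
from wavequant.msio import TARGET_COLUMNS
from wavequant.pipeline import quantify_frames

print(f"{'true L/H':>9} {'recovered':>10} {'rel. error':>11}")
for ratio in (0.5, 0.67, 1.0, 1.5, 2.0):
    peptide_ratios = []
    for k in range(20):
        spec = SyntheticSpec(noise_sigma=5.0, mixing_ratio=ratio, seed=1000 + 7 * k)
        spectra = generate_spectra(spec, mz_light=500.0, mz_heavy=504.0)
        targets = pd.DataFrame(
            [[f"PEP{k}", "PROT", 2, 500.0, 504.0, 65]], columns=TARGET_COLUMNS
        )
        _, proteins = quantify_frames(spectra, targets)
        if len(proteins):
            peptide_ratios.append(float(proteins.iloc[0]["final_ratio"]))
    final = protein_ratio(peptide_ratios).final_ratio
    print(f"{ratio:9.2f} {final:10.4f} {relative_error(final, ratio):10.2f}%")
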