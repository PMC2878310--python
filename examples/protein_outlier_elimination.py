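"""Aggregate peptide ratios into a protein ratio, pruning outliers.

A protein quantified by several peptides usually shows one or two wild
ratios (interference, misassignment). The aggregation keeps ratios
within median +/- sqrt(median) in the first round, then within
mean +/- sqrt(mean) of the survivors until the set stabilizes, and
reports the mean of what remains. The audit trail printed below shows
each round's interval and what it removed.
"""

from wavequant import protein_ratio

ratios = [1.0, 1.1, 0.9, 1.05, 5.0]
result = protein_ratio(ratios, protein="EXAMPLE_PROTEIN")

print(f"peptide ratios: {ratios}")
for rnd in result.rounds:
    print(
        f"round {rnd.number}: {rnd.center_kind}={rnd.center:.4f}, "
        f"keep [{rnd.low:.4f}, {rnd.high:.4f}], eliminated {rnd.eliminated or 'nothing'}"
    )
print(f"final protein ratio: {result.final_ratio:.4f} "
      f"(mean of {len(result.surviving_ratios)} surviving peptides)")
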