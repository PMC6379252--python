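"""Detect injected differential item functioning with the hybrid OLR scan.

Simulates a study-sized dataset in which women find every threshold of
the "crying" item 0.75 latent-trait units easier to cross (uniform DIF),
runs the iterative purification scan conditioned on EAP trait scores,
and prints the per-item decision together with the pseudo-R2 changes of
the flagged item.
"""

from gradedif import DIFInjection, SimulationSpec, dif_analysis, load_bdi2_bank, simulate_responses

bank = load_bdi2_bank()
data = simulate_responses(
    SimulationSpec(
        n_persons=12_677,
        item_bank=bank,
        seed=11,
        dif_spec=(DIFInjection(item_index=10, focal_group="F", threshold_shift=0.75),),
    )
)
report = dif_analysis(data, grouping="gender")

print(f"purification passes : {report.n_purification_iters} "
      f"(converged: {report.converged})")
print(f"flagged items       : {report.flagged_items}")
print(f"anchor items        : {len(report.anchor_set)} of {data.n_items}")

for res in report.results:
    if res.flagged:
        print(f"\nitem {res.item} ({bank.items[res.item - 1].label}): "
              f"{res.dif_type} DIF")
        for comp in ("1v3", "1v2", "2v3"):
            print(f"  McFadden dR2 {comp}: {res.delta(comp):.4f}")

print("\nThe 1v3 change above 0.02 flags the item; a large 1v2 change with a")
print("negligible 2v3 change classifies the effect as uniform — the group")
print("difference is constant across the severity continuum.")
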