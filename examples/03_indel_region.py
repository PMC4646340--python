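"""Detect a group-specific indel region in a protein alignment.

Simulates an alignment of 5 target and 20 background sequences in which
columns 70-129 hold a 60-residue insert present only in the target group
(the scale of the predator-specific insert in tryptophan 2,3-dioxygenase),
then scans column-wise gap occupancy to recover it and summarizes the
region's hydropathy and net charge.
"""

from panmarker import find_group_specific_regions, simulate_msa

msa, labels, truth = simulate_msa(
    n_target=5, n_background=20, core_len=150, insert_len=60,
    insert_start=70, sub_rate=0.05, seed=7)

regions = find_group_specific_regions(
    msa, labels, min_len=30,
    min_target_occupancy=0.9, max_background_occupancy=0.1)

print(f"planted insert: columns [{truth['insert_start']}, "
      f"{truth['insert_end']})")
for r in regions:
    print(f"detected region: columns [{r.start_col}, {r.end_col}), "
          f"{r.length} aa")
    print(f"  occupancy: target {r.occupancy_target:.2f}, "
          f"background {r.occupancy_background:.2f}")
    print(f"  consensus hydropathy {r.mean_hydropathy:+.2f} "
          f"± {r.sd_hydropathy:.2f} (Kyte-Doolittle; negative = hydrophilic)")
    print(f"  consensus net charge {r.net_charge:+.2f} at pH 7")
# The detected interval should equal the planted one exactly: substitutions
# change residues but never the gap structure the detector keys on.
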