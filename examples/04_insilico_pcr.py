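"""In-silico PCR with the degenerate predator-typing primer pair.

Simulates a panel of 3 templates carrying the primer pair's binding sites
141 bp apart and 5 random templates without sites, then predicts products.
The primer-inclusive product length is 23 + 141 + 16 = 180 bp, matching the
scale of the wet-lab product the primers were designed to yield.
"""

from panmarker import (Primer, expand_degenerate, find_amplicons,
                       simulate_templates)

fwd = Primer("TDO-F", "TAYGARYTVTGGTTYAARCARAT")
rev = Primer("TDO-R", "GGMGTCATSSTYTCVA")

count, variants = expand_degenerate(rev)
print(f"{rev.name} degeneracy: {count} concrete sequences "
      f"(enumerated: {len(variants)})")

templates, truth = simulate_templates(
    n_with_site=3, n_without=5, fwd=fwd, rev=rev, insert_gap=141, seed=11)
hits = find_amplicons(templates, fwd, rev, max_mismatches=0,
                      min_len=100, max_len=300)

print(f"{len(hits)} amplicon(s) on {len(templates)} templates "
      f"(expected: only the {len(truth['positives'])} positives)")
for h in hits:
    print(f"  {h.template_id}: [{h.start}, {h.end}) strand {h.strand}, "
          f"{h.length} bp, {h.fwd_mismatches}+{h.rev_mismatches} mismatches")
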