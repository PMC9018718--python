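"""Full wild-type vs mutant comparison on synthetic ensembles.

The wild type is the closed toy; the mutant carries a 10-residue tandem
duplication and sits in the open conformation (domain B displaced by
12 A).  Both are expanded into noisy 200-frame ensembles, time-averaged,
and compared end to end: distance-difference map, interface-pair loss,
per-residue displacement, solvent-accessibility shifts, hydrogen-bond
diff.
"""

from conformap import (ToySpec, apply_duplication, make_open_conformer,
                       make_two_domain_toy, simulate_frames)
from conformap.pipeline import AnalysisConfig, compare_alleles

closed, truth = make_two_domain_toy(ToySpec(seed=0))
opened = make_open_conformer(closed, truth.domain_b, (12.0, 0.0, 0.0),
                             linker_range=truth.linker_range)
mutant, rmap = apply_duplication(opened, 30, 39)

wt_e = simulate_frames(closed, 200, 0.5, 2.0, 0.5, seed=1)
mut_e = simulate_frames(mutant, 200, 0.5, 2.0, 0.5, seed=2)

config = AnalysisConfig(domain_a=truth.domain_a, domain_b=truth.domain_b,
                        superposition_frame="domain_a",
                        key_residues=(truth.marker_residue,))
bundle = compare_alleles(wt_e, mut_e, residue_map=rmap, config=config)
s = bundle["summary"]

marker = truth.marker_residue
print(f"interface pairs: {s['n_interface_pairs_wt']} (wt) -> "
      f"{s['n_interface_pairs_mut']} (mutant)")
print(f"cross-domain distance shift: "
      f"{s['diff_block_means_A']['cross_A_B']:+.2f} A "
      f"(intra-domain {s['diff_block_means_A']['intra_A']:+.3f} A)")
print(f"marker residue {marker} displacement: "
      f"{s['key_residue_displacement_A'][marker]:.2f} A")
kr = s["key_residue_rsa"][marker]
print(f"marker exposure: {kr['bin_wt']} -> {kr['bin_mut']}")
print(f"hydrogen bonds lost: {s['hbonds_lost']}")
print("\nThe mutant's open conformation abolishes the stabilising interface")
print("(pair count drops to zero), displaces every domain-B residue by the")
print("imposed 12 A, and exposes the buried marker — the signature of a")
print("duplication forcing a domain-out conformation.")
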