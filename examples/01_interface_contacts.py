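"""Find the hydrophobic contacts that hold a closed two-domain protein
together.

Builds the synthetic autoinhibited toy (domain A packed against domain B),
then detects residue pairs with at least six carbon-carbon contacts within
4 A — the criterion used to enumerate PH/kinase interface pairs.
"""

from conformap import ToySpec, find_hbonds, find_interface_pairs, make_two_domain_toy
from conformap.contacts import interface_pair_table

closed, truth = make_two_domain_toy(ToySpec(seed=0))
pairs = find_interface_pairs(closed, truth.domain_a, truth.domain_b)
print(interface_pair_table(pairs).to_string(index=False))

bonds = find_hbonds(closed)
(dres, datom), (ares, aatom) = truth.designated_hbond
cross = [b for b in bonds
         if (b.donor_residue in truth.domain_a) != (b.acceptor_residue in truth.domain_a)]
print(f"\n{len(pairs)} hydrophobic interface pairs; "
      f"{len(cross)} cross-domain hydrogen bonds "
      f"(designated: {dres}{datom}...{ares}{aatom})")
print("Each row is one residue pair bridging the domains; n_carbon_pairs")
print("counts carbon-carbon contacts within 4 A (>= 6 required).")
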