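"""Classify flagellin proteins by the TLR5-recognized consensus region.

Builds three synthetic flagellins around the 11-residue D1-domain consensus
(flagellin numbering 87-97): one fully conserved, one carrying the Q88D
substitution seen in two Roseburia flagellins (still predicted
pro-inflammatory, because positions 87/89/93/96 are what the verdict
requires), and one with R89A (not predicted).  Then clusters the published
E. rectale A1-86 amino-terminal 10-mers: four proteins are identical over
their first ten residues and the fifth (EUR_28730) conserves only four.
"""

import flagmet as fm
from flagmet.tlr5 import DEFAULT_CONSENSUS_SEQ

variants = {
    "conserved": DEFAULT_CONSENSUS_SEQ,
    "q88d": DEFAULT_CONSENSUS_SEQ[0] + "D" + DEFAULT_CONSENSUS_SEQ[2:],
    "r89a": DEFAULT_CONSENSUS_SEQ[:2] + "A" + DEFAULT_CONSENSUS_SEQ[3:],
}

print(f"consensus (positions 87-97): {DEFAULT_CONSENSUS_SEQ}")
for name, window in variants.items():
    protein = fm.make_flagellin(280, window, seed=1, protein_id=name)
    a = fm.assess_tlr5(protein)
    subs = ",".join(a.substitutions) or "none"
    print(f"{name:10s} window={a.aligned_region} conserved={a.n_critical_conserved}/5 "
          f"substitutions={subs} -> {a.verdict}")

print()
ref = fm.load_reference_flagellins()
a186 = ref[ref.species == "E. rectale A1-86"]
groups = fm.nterm_cluster([fm.ProteinRecord(r.locus_tag, r.nterm10 + "G" * 10)
                           for r in a186.itertuples()])
for mer, members in groups.items():
    print(f"N-terminal 10-mer {mer}: {len(members)} protein(s) ({', '.join(members)})")
shared = next(m for m, ids in groups.items() if len(ids) == 4)
print(f"EUR_28730 conserves {fm.nterm_identity('MKINRNMSAV', shared)}/10 "
      "residues of the shared N-terminus.")
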