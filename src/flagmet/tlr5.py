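"""TLR5 recognition-motif assessment of flagellin proteins.

Human TLR5 binds a conserved region of the flagellin D1 domain.  A short
consensus derived from pro-inflammatory beta/gamma-proteobacterial
flagellins covers flagellin-numbering positions 87-97; five residues inside
it — L87, Q88, R89, L93 and Q96 — are critical for TLR5 signalling and
filament polymerization.  A query flagellin is classified by locating the
best-matching ungapped 11-residue window and checking which critical
residues it conserves.

The verdict requires conservation of the four residues that are invariant
across pro-inflammatory flagellins (87, 89, 93, 96); substitution at 88
(e.g. Q88D, observed in two Roseburia flagellins) does not by itself revoke
the pro-inflammatory prediction.  Also provided are amino-terminal 10-mer
comparisons, used to match chemically sequenced protein bands to predicted
flagellin CDSs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence


class MotifError(ValueError):
    pass


#: Default 11-residue consensus of the TLR5-recognized D1 region of
#: beta/gamma-proteobacterial flagellins (flagellin numbering 87-97).
DEFAULT_CONSENSUS_SEQ = "LQRVRELAVQS"


@dataclass(frozen=True)
class Tlr5Consensus:
    consensus_seq: str = DEFAULT_CONSENSUS_SEQ
    window_position: int = 87  # flagellin-numbering position of the window start
    critical_residues: dict[int, str] = field(
        default_factory=lambda: {87: "L", 88: "Q", 89: "R", 93: "L", 96: "Q"})
    #: critical positions whose conservation is required for the verdict
    required_positions: frozenset[int] = frozenset({87, 89, 93, 96})

    def __post_init__(self):
        last = self.window_position + len(self.consensus_seq) - 1
        for pos in self.critical_residues:
            if not self.window_position <= pos <= last:
                raise MotifError(
                    f"critical position {pos} outside the consensus window "
                    f"{self.window_position}-{last}")
        for pos, aa in self.critical_residues.items():
            idx = pos - self.window_position
            if self.consensus_seq[idx] != aa:
                raise MotifError(
                    f"consensus residue at position {pos} is "
                    f"{self.consensus_seq[idx]!r}, critical map says {aa!r}")


class ConsensusWindow(NamedTuple):
    window: str
    offset: int      # 0-based offset in the query
    score: int       # identical positions out of len(consensus)


@dataclass(frozen=True)
class Tlr5Assessment:
    protein_id: str
    aligned_region: str
    offset: int
    conservation: dict[int, bool]      # critical position -> conserved?
    n_critical_conserved: int
    verdict: str                       # predicted_pro_inflammatory / not_predicted
    substitutions: tuple[str, ...]     # e.g. ("Q88D",)


def locate_consensus_region(protein, consensus: Tlr5Consensus = Tlr5Consensus()) -> ConsensusWindow:
    """Best-scoring ungapped window of the query against the consensus.

    The score is plain positional identity; ties are broken by the smallest
    offset.  This is an exhaustive window search, exact by construction.
    """
    seq = getattr(protein, "sequence", protein)
    k = len(consensus.consensus_seq)
    if len(seq) < k:
        raise MotifError(
            f"protein of {len(seq)} aa is shorter than the {k}-residue consensus")
    best = ConsensusWindow("", 0, -1)
    for off in range(len(seq) - k + 1):
        window = seq[off:off + k]
        score = sum(1 for a, b in zip(window, consensus.consensus_seq) if a == b)
        if score > best.score:
            best = ConsensusWindow(window, off, score)
    return best


def assess_tlr5(protein, consensus: Tlr5Consensus = Tlr5Consensus()) -> Tlr5Assessment:
    """Classify a flagellin as predicted pro-inflammatory or not.

    Conservation is evaluated at the five critical positions of the aligned
    window; the verdict requires all of the positions in
    ``consensus.required_positions`` (by default 87, 89, 93 and 96) to be
    conserved.  Substitutions at critical positions are reported in
    ``RefPosAlt`` notation (e.g. ``Q88D``).
    """
    pid = getattr(protein, "id", "?")
    window = locate_consensus_region(protein, consensus)
    conservation: dict[int, bool] = {}
    substitutions: list[str] = []
    for pos in sorted(consensus.critical_residues):
        ref = consensus.critical_residues[pos]
        obs = window.window[pos - consensus.window_position]
        ok = obs == ref
        conservation[pos] = ok
        if not ok:
            substitutions.append(f"{ref}{pos}{obs}")
    verdict = ("predicted_pro_inflammatory"
               if all(conservation[p] for p in consensus.required_positions)
               else "not_predicted")
    return Tlr5Assessment(
        protein_id=pid,
        aligned_region=window.window,
        offset=window.offset,
        conservation=conservation,
        n_critical_conserved=sum(conservation.values()),
        verdict=verdict,
        substitutions=tuple(substitutions),
    )


def nterm_identity(a: str, b: str) -> int:
    """Positional identity count between two amino-terminal 10-mers."""
    a = getattr(a, "sequence", a)[:]
    b = getattr(b, "sequence", b)[:]
    if len(a) != 10 or len(b) != 10:
        raise MotifError("N-terminal comparison requires two 10-residue strings")
    return sum(1 for x, y in zip(a, b) if x == y)


def nterm_cluster(proteins: Sequence) -> dict[str, list[str]]:
    """Partition proteins by their exact N-terminal 10-mer.

    Returns a mapping 10-mer -> list of protein ids, in first-seen order.
    """
    groups: dict[str, list[str]] = {}
    for p in proteins:
        seq = getattr(p, "sequence", p)
        pid = getattr(p, "id", seq)
        if len(seq) < 10:
            raise MotifError(f"protein {pid!r} shorter than 10 residues")
        groups.setdefault(seq[:10], []).append(pid)
    return groups
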