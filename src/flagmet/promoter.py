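"""Sigma-factor promoter and ribosome-binding-site scanning.

Upstream regions of flagellin CDSs are searched for sigma-28 (FliA, late
flagellar) and sigma-43 (housekeeping) -35/-10 promoter elements, and for
Shine-Dalgarno (AGGAGG-like) ribosome binding sites near the start codon.

Consensus strings are case encoded: uppercase positions are strongly
conserved, lowercase positions weakly conserved.  IUPAC degenerate letters
are allowed at either kind of position (e.g. ``M`` = A or C).  A scan policy
caps the number of mismatches tolerated per element at strong and at weak
positions separately.

Two stock policies are provided.  The default policy requires strong
positions to match exactly.  ``LENIENT_POLICY`` additionally tolerates one
mismatch per element at strong positions, which is the setting under which
every promoter in the published flagellin reference table (see
:mod:`flagmet.reference`) is recovered from its planted upstream sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd
import yaml

from .seqio import GeneFeature, GenomeRecord, reverse_complement

DASH = "–"  # placeholder used in report tables for "no call"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class LookupError_(KeyError):
    """Gene/genome mismatch during upstream extraction."""


@dataclass(frozen=True)
class ConsensusMotif:
    """A -35/-10 promoter consensus with its native spacer window.

    ``spacing_window`` is the (min, max) number of nucleotides strictly
    between the -35 and -10 elements in the source consensus; the scanner
    searches a wider window (see :class:`ScanPolicy`) and uses the native
    window only to flag canonical spacings.
    """

    sigma_label: int
    minus35: str
    minus10: str
    spacing_window: tuple[int, int]
    source: str = "general"

    def __post_init__(self):
        if not self.minus35 or not self.minus10:
            raise ValueError("consensus strings must be non-empty")
        lo, hi = self.spacing_window
        if hi < lo:
            raise ValueError("empty spacing window")


#: Butyrivibrio fibrisolvens consensus pair -- the default references for
#: promoter analysis in these Clostridium-cluster-XIVa commensals.
BFIB_SIGMA28 = ConsensusMotif(28, "TAAA", "MCGATAa", (16, 17), source="B_fibrisolvens")
BFIB_SIGMA43 = ConsensusMotif(43, "TTtACA", "cATAAT", (19, 19), source="B_fibrisolvens")
#: General bacterial consensus pair, kept for comparison runs.
GENERAL_SIGMA28 = ConsensusMotif(28, "TAAA", "CCGATAT", (15, 15), source="general")
GENERAL_SIGMA43 = ConsensusMotif(43, "TTGACA", "TATAAT", (15, 15), source="general")

DEFAULT_MOTIFS = [BFIB_SIGMA28, BFIB_SIGMA43]


@dataclass(frozen=True)
class ScanPolicy:
    """Mismatch and spacing tolerances for promoter scanning.

    The spacing window is deliberately wider (8-30 bp) than the consensus
    native windows because observed spacings in these genomes run well
    outside them; calls inside the native window carry ``canonical=True``.
    The default upstream search length of 400 bp covers the largest observed
    promoter-to-start distance (375 bp).
    """

    max_strong_mismatch: int = 0
    max_weak_mismatch: int = 1
    spacing_min: int = 8
    spacing_max: int = 30
    search_length: int = 400


DEFAULT_POLICY = ScanPolicy()
LENIENT_POLICY = ScanPolicy(max_strong_mismatch=1)


class Upstream(NamedTuple):
    sequence: str
    truncated: bool


@dataclass(frozen=True)
class PromoterCall:
    gene_id: str
    sigma_label: int
    minus35_seq: str
    minus10_seq: str
    spacing_35_10: int
    dist_10_to_start: int
    strong_mismatches: int
    weak_mismatches: int
    canonical: bool
    source: str = "general"


@dataclass(frozen=True)
class RbsCall:
    gene_id: str
    rbs_seq: str
    dist_to_start: int
    mismatches: int


def extract_upstream(genome: GenomeRecord, gene: GeneFeature, length: int) -> Upstream:
    """Coding-strand-oriented sequence ending just before the start codon.

    For reverse-strand genes the 3' flank (on the given sequence) is taken
    and reverse-complemented, so scanning always runs on the coding strand.
    Truncation at the genome/contig boundary is flagged.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if gene.genome_id != genome.id:
        raise LookupError_(f"gene {gene.id!r} does not belong to genome {genome.id!r}")
    if gene.strand == "+":
        lo = gene.start - 1 - length
        seq = genome.sequence[max(0, lo):gene.start - 1]
        return Upstream(seq, truncated=lo < 0)
    hi = gene.end + length
    seq = genome.sequence[gene.end:min(len(genome.sequence), hi)]
    return Upstream(reverse_complement(seq), truncated=hi > len(genome.sequence))


def element_mismatches(consensus: str, observed: str) -> tuple[int, int]:
    """(strong, weak) mismatch counts of ``observed`` against a case-encoded consensus."""
    if len(consensus) != len(observed):
        raise ValueError("observed element length must equal consensus length")
    strong = weak = 0
    for c, o in zip(consensus, observed.upper()):
        allowed = IUPAC[c.upper()]
        if o not in allowed:
            if c.isupper():
                strong += 1
            else:
                weak += 1
    return strong, weak


def _element_ok(consensus: str, observed: str, policy: ScanPolicy) -> tuple[int, int] | None:
    s, w = element_mismatches(consensus, observed)
    if s <= policy.max_strong_mismatch and w <= policy.max_weak_mismatch:
        return s, w
    return None


def scan_promoters(
    upstream: str,
    motifs: Iterable[ConsensusMotif] = DEFAULT_MOTIFS,
    policy: ScanPolicy = DEFAULT_POLICY,
    gene_id: str = "?",
) -> list[PromoterCall]:
    """Report every -35/-10 placement satisfying the policy.

    ``upstream`` must be coding-strand oriented and end at the base
    immediately before the start codon, so the distance from the -10 element
    to the start codon is the number of trailing bases after the element.
    Calls are sorted by that distance (ascending); the first call for a gene
    is its "primary" promoter.  A gene may legitimately receive calls for
    more than one sigma factor.
    """
    upstream = upstream.upper()
    calls: list[PromoterCall] = []
    for motif in motifs:
        n35, n10 = len(motif.minus35), len(motif.minus10)
        for p10 in range(len(upstream) - n10 + 1):
            obs10 = upstream[p10:p10 + n10]
            mm10 = _element_ok(motif.minus10, obs10, policy)
            if mm10 is None:
                continue
            dist = len(upstream) - (p10 + n10)
            for spacing in range(policy.spacing_min, policy.spacing_max + 1):
                p35 = p10 - spacing - n35
                if p35 < 0:
                    continue
                obs35 = upstream[p35:p35 + n35]
                mm35 = _element_ok(motif.minus35, obs35, policy)
                if mm35 is None:
                    continue
                lo, hi = motif.spacing_window
                calls.append(PromoterCall(
                    gene_id=gene_id,
                    sigma_label=motif.sigma_label,
                    minus35_seq=obs35.lower(),
                    minus10_seq=obs10.lower(),
                    spacing_35_10=spacing,
                    dist_10_to_start=dist,
                    strong_mismatches=mm35[0] + mm10[0],
                    weak_mismatches=mm35[1] + mm10[1],
                    canonical=lo <= spacing <= hi,
                    source=motif.source,
                ))
    calls.sort(key=lambda c: (c.dist_10_to_start, c.sigma_label, c.spacing_35_10))
    return calls


RBS_CONSENSUS = "AGGAGG"


def scan_rbs(
    upstream: str,
    max_gap: int = 20,
    max_mismatch: int = 1,
    gene_id: str = "?",
    consensus: str = RBS_CONSENSUS,
) -> RbsCall | None:
    """Best Shine-Dalgarno hexamer within ``max_gap`` bp of the start codon.

    "Best" is fewest mismatches against the consensus, ties broken by
    proximity to the start codon.  Returns ``None`` when no hexamer within
    the window meets the mismatch budget.
    """
    upstream = upstream.upper()
    n = len(consensus)
    best: RbsCall | None = None
    for p in range(len(upstream) - n, -1, -1):
        dist = len(upstream) - (p + n)
        if dist > max_gap:
            break
        obs = upstream[p:p + n]
        mm = sum(1 for c, o in zip(consensus, obs) if o not in IUPAC[c.upper()])
        if mm > max_mismatch:
            continue
        if best is None or (mm, dist) < (best.mismatches, best.dist_to_start):
            best = RbsCall(gene_id=gene_id, rbs_seq=obs, dist_to_start=dist, mismatches=mm)
    return best


REPORT_COLUMNS = [
    "gene_id", "sigma", "minus35", "minus10", "spacing_35_10",
    "dist_10_to_start", "rbs", "rbs_spacing", "rbs_mismatches",
]


def promoter_report(
    promoter_calls: dict[str, list[PromoterCall]],
    rbs_calls: dict[str, RbsCall | None],
    gene_order: list[str] | None = None,
) -> pd.DataFrame:
    """One row per (gene, promoter call); genes without calls get dash rows.

    Mirrors the layout of published flagellin promoter tables: promoter
    columns repeat per call while the RBS columns are shared across the rows
    of a gene.  Rows are ordered by gene, then by distance of the -10 element
    to the start codon.
    """
    genes = gene_order or sorted(set(promoter_calls) | set(rbs_calls))
    rows = []
    for gene in genes:
        rbs = rbs_calls.get(gene)
        rbs_cols = {
            "rbs": rbs.rbs_seq if rbs else DASH,
            "rbs_spacing": rbs.dist_to_start if rbs else DASH,
            "rbs_mismatches": rbs.mismatches if rbs else DASH,
        }
        calls = promoter_calls.get(gene, [])
        if not calls:
            rows.append({"gene_id": gene, "sigma": DASH, "minus35": DASH,
                         "minus10": DASH, "spacing_35_10": DASH,
                         "dist_10_to_start": DASH, **rbs_cols})
            continue
        for call in sorted(calls, key=lambda c: c.dist_10_to_start):
            rows.append({
                "gene_id": gene,
                "sigma": call.sigma_label,
                "minus35": call.minus35_seq,
                "minus10": call.minus10_seq,
                "spacing_35_10": call.spacing_35_10,
                "dist_10_to_start": call.dist_10_to_start,
                **rbs_cols,
            })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def summarize_promoter_spacings(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sigma summary (n, mean, min, max) of -10-to-start-codon distances.

    Accepts any table with ``sigma`` and ``dist_10_to_start`` columns,
    including the packaged reference table; dash/NA rows are ignored.
    """
    df = table[["sigma", "dist_10_to_start"]].copy()
    df = df[pd.to_numeric(df["dist_10_to_start"], errors="coerce").notna()]
    df["dist_10_to_start"] = df["dist_10_to_start"].astype(float)
    df["sigma"] = df["sigma"].astype(float).astype(int)
    grouped = df.groupby("sigma")["dist_10_to_start"]
    out = pd.DataFrame({
        "n": grouped.size(),
        "mean": grouped.mean(),
        "min": grouped.min(),
        "max": grouped.max(),
    })
    return out


def load_motifs(path=None) -> list[ConsensusMotif]:
    """Load consensus motifs from a YAML config (defaults to the packaged set)."""
    if path is None:
        from importlib.resources import files
        text = (files("flagmet") / "data" / "motifs.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    motifs = []
    for entry in raw["motifs"]:
        motifs.append(ConsensusMotif(
            sigma_label=int(entry["sigma_label"]),
            minus35=entry["minus35"],
            minus10=entry["minus10"],
            spacing_window=(int(entry["spacing_min"]), int(entry["spacing_max"])),
            source=entry.get("source", "general"),
        ))
    return motifs
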