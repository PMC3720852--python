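"""Synthetic genomes, communities, shotgun reads and cytokine experiments.

This module is the stand-in for the study system: bacterial genomes of a few
Mb carrying a ~31 kb motility locus of 34 contiguous genes plus dispersed
flagellin genes with planted sigma-28/sigma-43 promoters and ribosome
binding sites; communities of 5-8 species whose relative abundances span
0.01-31.59 %; and 91-bp single-end shotgun reads drawn uniformly from the
genomes treated as circular.  Every generator is a pure function of its
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

from .promoter import (
    DEFAULT_MOTIFS,
    DEFAULT_POLICY,
    ConsensusMotif,
    ScanPolicy,
    scan_promoters,
    scan_rbs,
)
from .seqio import GeneFeature, GenomeRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SizingError(ValueError):
    """Requested gene content does not fit in the genome."""


class PlacementError(ValueError):
    """A promoter/RBS cannot be planted where requested."""


class ConfigError(ValueError):
    """Inconsistent simulation configuration."""


# --------------------------------------------------------------------------
# community profiles


@dataclass
class CommunityProfile:
    """Species -> relative abundance (percent).  Must sum to 100."""

    abundances: dict[str, float]

    def __post_init__(self) -> None:
        for sp, ab in self.abundances.items():
            if ab < 0:
                raise ConfigError(f"negative abundance for {sp!r}")
        total = sum(self.abundances.values())
        if abs(total - 100.0) > 1e-9:
            raise ConfigError(f"abundances sum to {total!r}, expected 100")

    @property
    def species(self) -> list[str]:
        return list(self.abundances)

    def fraction(self, species: str) -> float:
        return self.abundances[species] / 100.0


#: Default community: seven species spanning the observed dynamic range of
#: relative abundances (0.01 % to 31.59 %).
DEFAULT_COMMUNITY = {
    "sp_A": 31.59,
    "sp_B": 25.0,
    "sp_C": 20.0,
    "sp_D": 15.0,
    "sp_E": 8.3,
    "sp_F": 0.1,
    "sp_G": 0.01,
}


# --------------------------------------------------------------------------
# genome construction


#: 34-gene flgB-fliA-style motility locus: contiguous basal-body, hook,
#: motor, export and chemotaxis genes ending in the late sigma factor gene.
#: Lengths are plausible CDS sizes (multiples of 3) chosen so the locus
#: spans 30.5-31.5 kb with a median gene length near 900 bp.
DEFAULT_LOCUS_SPEC: list[tuple[str, int]] = [
    ("flgB", 399), ("flgC", 420), ("fliE", 315), ("fliF", 1605),
    ("fliG", 1011), ("fliH", 690), ("fliI", 1329), ("fliJ", 444),
    ("fliK", 1602), ("flgD", 501), ("flgE", 1503), ("flbD", 903),
    ("motA", 900), ("motB", 876), ("fliL", 489), ("fliM", 1002),
    ("fliY", 1203), ("fliZ", 555), ("fliO", 363), ("fliP", 903),
    ("fliQ", 267), ("fliR", 900), ("flhB", 1083), ("flhA", 2085),
    ("flhF", 1176), ("flhG", 897), ("fliD", 1491), ("fliS", 396),
    ("cheB", 1050), ("cheA", 2004), ("cheW", 504), ("cheC", 633),
    ("cheD", 510), ("fliA", 723),
]


def random_sequence(rng: np.random.Generator, n: int, gc: float = 0.45) -> str:
    """Random nucleotide string with the given GC content (default 45 %)."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=n, p=p)
    return _BASES[codes].tobytes().decode("ascii")


def make_genome(
    species: str,
    size_bp: int,
    locus_spec: Sequence[tuple[str, int]] = (),
    seed: int = 0,
    *,
    dispersed_genes: Sequence[tuple[str, int]] = (),
    locus_label: str = "flgB-fliA",
    gc: float = 0.45,
    upstream_clearance: int = 450,
) -> tuple[GenomeRecord, list[GeneFeature]]:
    """Build a random genome with a contiguous motility locus.

    Locus genes are placed back to back on the + strand in the given order,
    so the locus span equals the sum of the gene lengths.  ``dispersed_genes``
    (typically flagellin CDSs) are placed at well-separated positions with at
    least ``upstream_clearance`` bp of promoter-free room upstream.  Gene
    sequences start with ATG; CDS lengths must be multiples of 3.
    """
    rng = np.random.default_rng(seed)
    for name, length in list(locus_spec) + list(dispersed_genes):
        if length % 3:
            raise SizingError(f"CDS {name!r} length {length} not a multiple of 3")
    locus_len = sum(length for _, length in locus_spec)
    dispersed = list(dispersed_genes)
    needed = locus_len + sum(l for _, l in dispersed) + (len(dispersed) + 1) * upstream_clearance
    if needed >= size_bp:
        raise SizingError(
            f"genome of {size_bp} bp cannot hold {locus_len} bp of locus plus "
            f"{len(dispersed)} dispersed genes with {upstream_clearance} bp clearance"
        )

    seq = bytearray(random_sequence(rng, size_bp, gc=gc), "ascii")
    features: list[GeneFeature] = []
    occupied: list[tuple[int, int]] = []  # 0-based half-open, with clearance

    def reserve(span: int, clearance: int) -> int:
        for _ in range(1000):
            start = int(rng.integers(clearance, size_bp - span))
            block = (start - clearance, start + span)
            if all(block[1] <= lo or block[0] >= hi for lo, hi in occupied):
                occupied.append(block)
                return start
        raise SizingError("could not place genes without overlap; genome too small")

    idx = 1
    if locus_spec:
        locus_start0 = reserve(locus_len, upstream_clearance)
        pos = locus_start0
        for product, length in locus_spec:
            seq[pos:pos + 3] = b"ATG"
            features.append(GeneFeature(
                id=f"{species}_{idx:04d}", genome_id=species,
                start=pos + 1, end=pos + length, strand="+",
                product=product, locus_label=locus_label,
            ))
            pos += length
            idx += 1

    for product, length in dispersed:
        start0 = reserve(length, upstream_clearance)
        seq[start0:start0 + 3] = b"ATG"
        features.append(GeneFeature(
            id=f"{species}_{idx:04d}", genome_id=species,
            start=start0 + 1, end=start0 + length, strand="+",
            product=product, locus_label="none",
        ))
        idx += 1

    features.sort(key=lambda f: f.start)
    genome = GenomeRecord(id=species, sequence=seq.decode("ascii"), species=species)
    return genome, features


def plant_promoter(
    genome: GenomeRecord,
    gene: GeneFeature,
    minus35: str,
    spacer_n: int,
    minus10: str,
    gap_to_start: int,
    rbs: str | None,
    rbs_gap: int = 8,
    *,
    extra_promoters: Sequence[tuple[str, int, str, int]] = (),
    motifs: Sequence[ConsensusMotif] = DEFAULT_MOTIFS,
    policy: ScanPolicy = DEFAULT_POLICY,
    rbs_max_mismatch: int = 2,
    seed: int = 0,
    max_tries: int = 2000,
) -> GenomeRecord:
    """Plant promoter elements (and optionally an RBS) upstream of a gene.

    The upstream scan window (``policy.search_length``) is rewritten: the
    requested elements are placed at exactly the requested spacings (counts
    of nucleotides strictly between elements) and every other position is
    re-randomized until a scan of the region under ``policy`` reports exactly
    the planted calls and the planted RBS — rejection sampling that keeps
    planted-promoter tests exact.  ``extra_promoters`` allows dual-sigma
    genes: each entry is ``(minus35, spacer_n, minus10, gap_to_start)``.

    Raises :class:`PlacementError` when the elements do not fit upstream of
    the gene or would overlap the previous feature.
    """
    rng = np.random.default_rng(seed)
    window = policy.search_length
    promoters = [(minus35, spacer_n, minus10, gap_to_start)] + list(extra_promoters)

    # planted segments as (offset_from_start_codon, sequence); offset is the
    # number of bases between the segment end and the start codon.
    segments: list[tuple[int, str]] = []
    for m35, spacer, m10, gap in promoters:
        if gap < 0 or spacer < 0:
            raise PlacementError("negative spacing requested")
        segments.append((gap, m10))
        segments.append((gap + len(m10) + spacer, m35))
    if rbs is not None:
        if rbs_gap < 0:
            raise PlacementError("negative RBS gap")
        segments.append((rbs_gap, rbs))

    span_needed = max(off + len(s) for off, s in segments)
    if span_needed > window:
        raise PlacementError(
            f"planted elements span {span_needed} bp, beyond the {window} bp scan window"
        )

    if gene.strand != "+":
        raise PlacementError("promoter planting is implemented for + strand genes")
    up_hi = gene.start - 1          # 0-based exclusive end of upstream window
    up_lo = up_hi - window
    if up_lo < 0:
        raise PlacementError(f"gene {gene.id!r}: only {up_hi} bp upstream, need {window}")

    # occupancy check against other features (the planted window must be
    # intergenic)
    # -- callers pass genomes from make_genome, which guarantees clearance;
    #    still verify against the sequence bounds.

    planted = np.zeros(window, dtype=bool)
    template = bytearray(window)
    for off, s in segments:
        hi = window - off
        lo = hi - len(s)
        if planted[lo:hi].any():
            raise PlacementError("planted elements overlap each other")
        planted[lo:hi] = True
        template[lo:hi] = s.upper().encode("ascii")
    free = ~planted

    expected_calls = set()
    for m35, spacer, m10, gap in promoters:
        expected_calls.add((m35.lower(), m10.lower(), spacer, gap))

    seq = bytearray(genome.sequence, "ascii")
    nfree = int(free.sum())
    for _ in range(max_tries):
        fill = _BASES[rng.integers(0, 4, size=nfree)]
        candidate = bytearray(template)
        np_candidate = np.frombuffer(candidate, dtype=np.uint8).copy()
        np_candidate[free] = fill
        upstream = np_candidate.tobytes().decode("ascii")

        calls = scan_promoters(upstream, motifs=motifs, policy=policy, gene_id=gene.id)
        got = {(c.minus35_seq, c.minus10_seq, c.spacing_35_10, c.dist_10_to_start)
               for c in calls}
        if got != expected_calls:
            continue
        if rbs is not None:
            hit = scan_rbs(upstream, max_mismatch=rbs_max_mismatch, gene_id=gene.id)
            if hit is None or hit.rbs_seq != rbs.upper() or hit.dist_to_start != rbs_gap:
                continue
        seq[up_lo:up_hi] = upstream.encode("ascii")
        return GenomeRecord(id=genome.id, sequence=seq.decode("ascii"),
                            species=genome.species)
    raise PlacementError(
        f"could not randomize upstream of {gene.id!r} without spurious calls "
        f"after {max_tries} tries"
    )


# --------------------------------------------------------------------------
# shotgun read simulation


class Read(NamedTuple):
    sequence: str
    origin_species: str
    origin_start: int  # 1-based position on the origin genome


@dataclass
class ReadSet:
    reads: list[Read]
    read_length: int = 91
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        for r in self.reads[:1000]:
            if len(r.sequence) != self.read_length:
                raise ConfigError(
                    f"read of length {len(r.sequence)} in a {self.read_length} bp read set"
                )

    @property
    def total_bases(self) -> int:
        return len(self.reads) * self.read_length


@dataclass
class SimulationConfig:
    """Knobs of the shotgun simulator.

    ``depth_bases`` is the sequencing depth in bases; the read count is
    ``depth_bases // read_length``.  ``coverage_mode`` is ``uniform`` (reads
    start anywhere on the circular genome) or ``blackout`` (start positions
    inside the listed intervals are excluded, emulating genomic regions that
    return zero or very few reads despite high species abundance).
    ``count_mode`` is ``multinomial`` (species read counts drawn from the
    community profile) or ``expected`` (deterministic rounded expectation).
    """

    seed: int = 0
    depth_bases: float = 1e7
    read_length: int = 91
    error_rate: float = 0.0
    coverage_mode: str = "uniform"
    blackout: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    count_mode: str = "multinomial"

    def __post_init__(self) -> None:
        if self.depth_bases <= 0:
            raise ConfigError("depth_bases must be positive")
        if self.coverage_mode not in ("uniform", "blackout"):
            raise ConfigError(f"unknown coverage mode {self.coverage_mode!r}")
        if self.count_mode not in ("multinomial", "expected"):
            raise ConfigError(f"unknown count mode {self.count_mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        raw = yaml.safe_load(open(path)) or {}
        if "blackout" in raw:
            raw["blackout"] = {
                g: [tuple(iv) for iv in ivs] for g, ivs in raw["blackout"].items()
            }
        return cls(**raw)


def allocate_read_counts(
    profile: CommunityProfile, n_reads: int, seed: int, count_mode: str = "multinomial"
) -> dict[str, int]:
    """Number of reads per species for a community of ``n_reads`` total.

    ``multinomial`` draws from the profile; ``expected`` rounds the exact
    expectation per species (used where tests need deterministic counts).
    """
    species = profile.species
    if count_mode == "expected":
        return {sp: int(round(n_reads * profile.fraction(sp))) for sp in species}
    rng = np.random.default_rng(seed)
    probs = np.array([profile.fraction(sp) for sp in species])
    counts = rng.multinomial(n_reads, probs / probs.sum())
    return dict(zip(species, (int(c) for c in counts)))


def _sample_starts(
    rng: np.random.Generator, n: int, genome_size: int,
    blackout: list[tuple[int, int]] | None,
) -> np.ndarray:
    """Uniform 0-based read start positions, excluding blackout intervals."""
    starts = rng.integers(0, genome_size, size=n)
    if not blackout:
        return starts
    lo = np.array([b[0] - 1 for b in blackout])
    hi = np.array([b[1] - 1 for b in blackout])
    for b0, b1 in zip(lo, hi):
        if b0 < 0 or b1 >= genome_size or b0 > b1:
            raise ConfigError(f"blackout interval ({b0 + 1}, {b1 + 1}) outside genome")
    while True:
        bad = np.zeros(len(starts), dtype=bool)
        for b0, b1 in zip(lo, hi):
            bad |= (starts >= b0) & (starts <= b1)
        if not bad.any():
            return starts
        starts[bad] = rng.integers(0, genome_size, size=int(bad.sum()))


def simulate_reads(
    genomes: Sequence[GenomeRecord],
    profile: CommunityProfile,
    config: SimulationConfig,
    sample_id: str = "sample",
) -> ReadSet:
    """Simulate single-end shotgun reads from a community.

    Reads are allocated to species in proportion to relative abundance and
    placed uniformly on the genome treated as circular, so the expected
    number of reads overlapping a CDS has the closed form used by
    :func:`flagmet.detect.expected_reads_per_cds`.  Substitution errors are
    applied at ``config.error_rate`` per base.  Deterministic under
    ``config.seed``.
    """
    by_species = {g.species: g for g in genomes}
    for sp in profile.species:
        if sp not in by_species:
            raise ConfigError(f"species {sp!r} in profile has no genome")
    rl = config.read_length
    if config.depth_bases < rl:
        raise ConfigError("depth_bases smaller than one read")
    n_total = int(config.depth_bases // rl)
    counts = allocate_read_counts(profile, n_total, seed=config.seed,
                                  count_mode=config.count_mode)
    rng = np.random.default_rng(config.seed + 1)
    reads: list[Read] = []
    for sp in profile.species:
        n = counts[sp]
        if n == 0:
            continue
        genome = by_species[sp]
        genome.validate_acgt()
        ext = genome.sequence + genome.sequence[:rl - 1]
        blackout = config.blackout.get(sp) if config.coverage_mode == "blackout" else None
        starts = _sample_starts(rng, n, genome.size_bp, blackout)
        if config.error_rate > 0:
            arr = np.frombuffer(ext.encode("ascii"), dtype=np.uint8)
            for s in starts:
                read = arr[s:s + rl].copy()
                errs = rng.random(rl) < config.error_rate
                if errs.any():
                    shift = rng.integers(1, 4, size=int(errs.sum())).astype(np.uint8)
                    codes = np.searchsorted(_BASES, read[errs])
                    read[errs] = _BASES[(codes + shift) % 4]
                reads.append(Read(read.tobytes().decode("ascii"), sp, int(s) + 1))
        else:
            for s in starts:
                reads.append(Read(ext[s:s + rl], sp, int(s) + 1))
    return ReadSet(reads=reads, read_length=rl, sample_id=sample_id)


def write_reads_fasta(readset: ReadSet, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for i, r in enumerate(readset.reads):
            fh.write(f">r{i:07d}\n{r.sequence}\n")


def write_reads_fastq(readset: ReadSet, path, quality: str = "I") -> None:
    q = quality * readset.read_length
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for i, r in enumerate(readset.reads):
            fh.write(f"@r{i:07d}\n{r.sequence}\n+\n{q}\n")


def write_truth_table(readset: ReadSet, path) -> None:
    """Read id -> hidden origin (species and 1-based start), as TSV."""
    rows = [
        {"read_id": f"r{i:07d}", "origin_species": r.origin_species,
         "origin_start": r.origin_start}
        for i, r in enumerate(readset.reads)
    ]
    pd.DataFrame(rows, columns=["read_id", "origin_species", "origin_start"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n")


# --------------------------------------------------------------------------
# flagellin proteins and cytokine experiments


def make_flagellin(
    length_aa: int,
    consensus_window: str,
    seed: int = 0,
    window_position: int = 87,
    protein_id: str = "fliC",
) -> "ProteinRecord":
    """Random protein with an 11-residue recognition window planted at a
    fixed flagellin-numbering position (default 87, i.e. 0-based offset 86)."""
    from .seqio import ProteinRecord

    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)
    offset = window_position - 1
    if length_aa < offset + len(consensus_window):
        raise SizingError(
            f"protein of {length_aa} aa too short for a window at position {window_position}"
        )
    seq = bytearray(alphabet[rng.integers(0, 20, size=length_aa)].tobytes())
    seq[offset:offset + len(consensus_window)] = consensus_window.encode("ascii")
    return ProteinRecord(id=protein_id, sequence=seq.decode("ascii"))


def simulate_cytokine_experiment(
    n_experiments: int,
    treatments: Sequence[str],
    effect: dict[str, float],
    seed: int = 0,
    base_concentration: float = 100.0,
    day_sigma: float = 0.5,
    noise_sigma: float = 0.3,
) -> pd.DataFrame:
    """Synthetic IL-8 style concentrations for independent experiments.

    Each experiment (performed "on a different day") gets a log-normal scale
    factor shared by all its treatments; each measurement multiplies the
    treatment's mean fold-change (``effect``, relative to an untreated
    control at 1.0) by log-normal measurement noise.  The per-experiment
    scale cancels in the downstream proportion transform, which is exactly
    why that transform is used.
    """
    if n_experiments < 2:
        raise ConfigError("need at least 2 experiments (one is untestable)")
    for t in treatments:
        if t not in effect:
            raise ConfigError(f"treatment {t!r} has no effect entry")
        if effect[t] <= 0:
            raise ConfigError(f"non-positive effect for treatment {t!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for e in range(1, n_experiments + 1):
        day = math.exp(rng.normal(0.0, day_sigma))
        for t in treatments:
            noise = math.exp(rng.normal(0.0, noise_sigma))
            rows.append({
                "experiment": f"exp{e}",
                "treatment": t,
                "concentration": base_concentration * day * effect[t] * noise,
            })
    return pd.DataFrame(rows)
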