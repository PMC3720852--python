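"""Metagenome-side computations: read mapping to target CDSs, depth
normalization, presence thresholds, coverage arithmetic, marker-based
abundance estimation and the contig species-assignment rule.

Mapping is substitution-only and end-to-end: a read maps wherever it aligns
over its full length with at most ``max_mismatch`` substitutions.  The
mapper is seeded with ``max_mismatch + 1`` disjoint k-mers, which makes it
complete for this alignment model (any placement with <= max_mismatch
substitutions leaves at least one seed exact).  Reads with several equally
good placements are counted once, at the first placement by (genome,
coordinate); a read overlapping two CDSs counts for both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .seqio import GeneFeature, GenomeRecord
from .synth import CommunityProfile, ConfigError, ReadSet

MEAN_SEQUENCING_DEPTH = 4.79e9  # bases per metagenome, the study-scale mean

#: presence thresholds on normalized mapped-read counts: >= 10 reads call a
#: CDS "present"; >= 10**1.5 (~31.6) call it "strong" (strongly present).
THETA_PRESENT = 10.0
THETA_STRONG = 10 ** 1.5

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i


def _encode(seq: str) -> np.ndarray:
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        raise ConfigError("sequence contains non-ACGT characters; cannot map")
    return arr


class Placement(NamedTuple):
    genome_id: str
    start: int        # 0-based start on the (circular) genome
    mismatches: int


class ReferenceIndex:
    """Exact k-mer index over one or more circular genomes.

    Builds a sorted array of k-mer hashes per genome; lookups are
    binary searches.  Reusable across read sets, which matters when the same
    reference is queried for many simulated samples.
    """

    K = 16

    def __init__(self, genomes: Sequence[GenomeRecord], read_length: int = 91,
                 max_mismatch: int = 2):
        if (max_mismatch + 1) * self.K > read_length:
            raise ConfigError(
                f"max_mismatch={max_mismatch} needs {(max_mismatch + 1) * self.K} bp "
                f"of seeds but reads are {read_length} bp"
            )
        self.read_length = read_length
        self.max_mismatch = max_mismatch
        self.seed_offsets = [i * self.K for i in range(max_mismatch + 1)]
        self.genomes = list(genomes)
        self._ext: list[np.ndarray] = []
        self._sorted_hashes: list[np.ndarray] = []
        self._positions: list[np.ndarray] = []
        for g in self.genomes:
            if g.size_bp < read_length:
                raise ConfigError(f"genome {g.id!r} shorter than the read length")
            ext = _encode(g.sequence + g.sequence[:read_length - 1]).astype(np.int64)
            hashes = self._kmer_hashes(ext, g.size_bp)
            order = np.argsort(hashes, kind="stable")
            self._ext.append(ext)
            self._sorted_hashes.append(hashes[order])
            self._positions.append(order.astype(np.int64))

    def _kmer_hashes(self, codes: np.ndarray, n: int) -> np.ndarray:
        h = np.zeros(n, dtype=np.int64)
        for j in range(self.K):
            h = h * 4 + codes[j:j + n]
        return h

    def place(self, reads: Iterable[str]) -> list[Placement | None]:
        """Best end-to-end placement per read (None when unmapped)."""
        seqs = list(reads)
        if not seqs:
            return []
        rl = self.read_length
        mat = np.vstack([_encode(s) for s in seqs]).astype(np.int64)
        n = len(seqs)
        # seed hashes, one column per seed offset
        seed_h = np.zeros((n, len(self.seed_offsets)), dtype=np.int64)
        for col, off in enumerate(self.seed_offsets):
            h = np.zeros(n, dtype=np.int64)
            for j in range(self.K):
                h = h * 4 + mat[:, off + j]
            seed_h[:, col] = h

        results: list[Placement | None] = [None] * n
        best_mm = np.full(n, self.max_mismatch + 1, dtype=np.int64)
        for gi, genome in enumerate(self.genomes):
            hashes = self._sorted_hashes[gi]
            positions = self._positions[gi]
            ext = self._ext[gi]
            G = genome.size_bp
            lo = np.searchsorted(hashes, seed_h, side="left")
            hi = np.searchsorted(hashes, seed_h, side="right")
            for i in range(n):
                cands: set[int] = set()
                for col, off in enumerate(self.seed_offsets):
                    for p in positions[lo[i, col]:hi[i, col]]:
                        cands.add((int(p) - off) % G)
                if not cands:
                    continue
                read = mat[i]
                for start in sorted(cands):
                    mm = int(np.count_nonzero(ext[start:start + rl] != read))
                    if mm < best_mm[i]:
                        best_mm[i] = mm
                        results[i] = Placement(genome.id, start, mm)
                        if mm == 0:
                            break
        return results


@dataclass
class MappedCounts:
    """Raw mapped-read counts per (gene, sample) plus sequencing depths."""

    counts: pd.DataFrame                      # genes x samples, int
    sample_depths: dict[str, float]
    mean_depth: float = MEAN_SEQUENCING_DEPTH


@dataclass
class DetectabilityMatrix:
    """Normalized counts and three-level presence calls per (gene, sample)."""

    normalized: pd.DataFrame                  # genes x samples, float
    presence: pd.DataFrame | None = None      # {absent, present, strong}
    thresholds: tuple[float, float] = (THETA_PRESENT, THETA_STRONG)


def _count_feature_overlaps(
    placements: Sequence[Placement | None],
    features: Sequence[GeneFeature],
    genomes: Sequence[GenomeRecord],
    read_length: int,
) -> pd.Series:
    sizes = {g.id: g.size_bp for g in genomes}
    starts_by_genome: dict[str, list[int]] = {}
    for p in placements:
        if p is not None:
            starts_by_genome.setdefault(p.genome_id, []).append(p.start)
    arrays = {g: np.asarray(v, dtype=np.int64) for g, v in starts_by_genome.items()}
    counts = {}
    for feat in features:
        starts = arrays.get(feat.genome_id)
        if starts is None or len(starts) == 0:
            counts[feat.id] = 0
            continue
        G = sizes[feat.genome_id]
        # a read of length rl starting at s (0-based, circular) overlaps the
        # CDS [start-1, end-1] iff s falls in a window of cds_len + rl - 1
        # positions ending at the CDS 3' end
        window = feat.length_bp + read_length - 1
        lo = (feat.start - 1) - (read_length - 1)
        counts[feat.id] = int(np.count_nonzero((starts - lo) % G < window))
    return pd.Series(counts, dtype=int)


def map_reads(
    reads: ReadSet,
    features: Sequence[GeneFeature],
    genomes: Sequence[GenomeRecord],
    max_mismatch: int = 2,
    sample_depths: dict[str, float] | None = None,
    mean_depth: float = MEAN_SEQUENCING_DEPTH,
    index: ReferenceIndex | None = None,
) -> MappedCounts:
    """Map a read set end-to-end and count reads per target CDS.

    A read is credited to every CDS its best placement overlaps by at least
    one base.  Pass a prebuilt :class:`ReferenceIndex` to amortize index
    construction across samples.  ``sample_depths`` defaults to the read
    set's own total bases.
    """
    if index is None:
        index = ReferenceIndex(genomes, read_length=reads.read_length,
                               max_mismatch=max_mismatch)
    placements = index.place(r.sequence for r in reads.reads)
    col = _count_feature_overlaps(placements, features, genomes, reads.read_length)
    counts = col.to_frame(name=reads.sample_id)
    depths = sample_depths or {reads.sample_id: float(reads.total_bases)}
    return MappedCounts(counts=counts, sample_depths=depths, mean_depth=mean_depth)


def combine_counts(per_sample: Sequence[MappedCounts]) -> MappedCounts:
    """Merge single-sample counts into one genes x samples table."""
    counts = pd.concat([mc.counts for mc in per_sample], axis=1).fillna(0).astype(int)
    depths: dict[str, float] = {}
    for mc in per_sample:
        depths.update(mc.sample_depths)
    return MappedCounts(counts=counts, sample_depths=depths,
                        mean_depth=per_sample[0].mean_depth)


def normalize_counts(mc: MappedCounts) -> DetectabilityMatrix:
    """Scale raw counts by (mean depth / sample depth), sample by sample.

    This makes counts from metagenomes of unequal sequencing depth
    comparable; it is the identity when every sample was sequenced at
    exactly the mean depth.
    """
    cols = {}
    for sample in mc.counts.columns:
        if sample not in mc.sample_depths:
            raise ConfigError(f"no sequencing depth recorded for sample {sample!r}")
        cols[sample] = mc.counts[sample] * (mc.mean_depth / mc.sample_depths[sample])
    return DetectabilityMatrix(normalized=pd.DataFrame(cols))


def call_presence(
    dm: DetectabilityMatrix,
    theta_present: float | None = None,
    theta_strong: float | None = None,
) -> DetectabilityMatrix:
    """Three-level presence call per cell: absent / present / strong.

    A CDS is "present" in a sample when its normalized count is >= 10 and
    "strong" (strongly suggesting the target sequence is in the database)
    when >= 10**1.5 (~31.6); both thresholds are inclusive and configurable.
    """
    t1 = THETA_PRESENT if theta_present is None else theta_present
    t2 = THETA_STRONG if theta_strong is None else theta_strong
    norm = dm.normalized
    presence = pd.DataFrame(
        np.where(norm >= t2, "strong", np.where(norm >= t1, "present", "absent")),
        index=norm.index, columns=norm.columns,
    )
    return DetectabilityMatrix(normalized=norm, presence=presence, thresholds=(t1, t2))


def locus_presence_fraction(dm: DetectabilityMatrix,
                            features: Sequence[GeneFeature]) -> pd.DataFrame:
    """Per (locus, sample) fraction of member genes called present or better."""
    if dm.presence is None:
        raise ValueError("call_presence first")
    rows = {}
    by_locus: dict[str, list[str]] = {}
    for f in features:
        by_locus.setdefault(f.locus_label, []).append(f.id)
    for locus, gene_ids in by_locus.items():
        sub = dm.presence.loc[[g for g in gene_ids if g in dm.presence.index]]
        rows[locus] = (sub != "absent").mean()
    return pd.DataFrame(rows).T


def expected_reads_per_cds(
    depth: float,
    abundance: float,
    genome_size: float,
    cds_length: float,
    read_length: float = 91,
) -> float:
    """Closed-form expected mapped reads for one CDS.

    With ``n = depth * abundance% / read_length`` reads placed uniformly on a
    circular genome, a read overlaps the CDS by >= 1 bp iff its start falls
    in a window of ``cds_length + read_length - 1`` positions, hence::

        E = n * (cds_length + read_length - 1) / genome_size

    Detectability is therefore linear in both CDS length and species
    relative abundance.
    """
    n_reads = depth * (abundance / 100.0) / read_length
    return n_reads * (cds_length + read_length - 1) / genome_size


def genome_coverage(metagenome_size_mb: float, abundance: float,
                    genome_size_mb: float) -> float:
    """Fold coverage of a target genome in a metagenome.

    Metagenome size times the species' relative abundance (percent, used as
    a fraction) divided by the average target genome size: 1 % of a 4,000 Mb
    metagenome over a 4 Mb genome is 10x.
    """
    if metagenome_size_mb <= 0 or genome_size_mb <= 0 or abundance < 0:
        raise ValueError("arguments must be positive (abundance >= 0)")
    return metagenome_size_mb * (abundance / 100.0) / genome_size_mb


@dataclass
class CoverageEstimate:
    species: str
    sample: str
    metagenome_size_mb: float
    rel_abundance: float
    genome_size_mb: float
    fold_coverage: float = field(init=False)

    def __post_init__(self) -> None:
        self.fold_coverage = genome_coverage(
            self.metagenome_size_mb, self.rel_abundance, self.genome_size_mb)


def estimate_abundance(
    reads: ReadSet,
    markers: dict[str, list[GeneFeature]],
    genomes: Sequence[GenomeRecord],
    max_mismatch: int = 2,
    index: ReferenceIndex | None = None,
) -> CommunityProfile:
    """Marker-counting relative abundance estimator.

    Reads are mapped to the reference genomes; for each species the density
    of reads over its marker genes (reads per marker kb) is computed and the
    densities are renormalized to sum to 100 %.  Marker genes must be unique
    to their species within the reference set.  A read set with zero marker
    hits yields a uniform profile with a warning (pipelines must proceed on
    empty samples).
    """
    all_markers = [f for feats in markers.values() for f in feats]
    mc = map_reads(reads, all_markers, genomes, max_mismatch=max_mismatch, index=index)
    densities = {}
    for sp, feats in markers.items():
        total_kb = sum(f.length_bp for f in feats) / 1000.0
        if total_kb == 0:
            raise ConfigError(f"species {sp!r} has zero total marker length")
        hits = int(mc.counts.loc[[f.id for f in feats]].sum().sum())
        densities[sp] = hits / total_kb
    total = sum(densities.values())
    if total == 0:
        warnings.warn("no reads mapped to any marker; returning a uniform profile")
        k = len(densities)
        return CommunityProfile({sp: 100.0 / k for sp in densities})
    return CommunityProfile({sp: 100.0 * d / total for sp, d in densities.items()})


def heat_matrix(
    dm: DetectabilityMatrix,
    features: Sequence[GeneFeature],
    order: str = "by_length",
    sample_order: Sequence[str] | None = None,
    path=None,
) -> pd.DataFrame:
    """log10(1 + normalized count) matrix, samples x genes, for heat plots.

    ``order="by_length"`` sorts gene columns by increasing CDS length;
    ``order="by_locus"`` keeps locus members contiguous in their gene-order
    (input feature order within each locus).  ``sample_order`` typically
    sorts samples by the species' relative abundance.  When ``path`` is
    given, a heat map image is written with matplotlib.
    """
    feats = [f for f in features if f.id in dm.normalized.index]
    if order == "by_length":
        feats = sorted(feats, key=lambda f: (f.length_bp, f.id))
    elif order == "by_locus":
        by_locus: dict[str, list[GeneFeature]] = {}
        for f in feats:
            by_locus.setdefault(f.locus_label, []).append(f)
        feats = [f for locus in by_locus.values() for f in locus]
    else:
        raise ValueError(f"unknown ordering {order!r} (use by_length or by_locus)")
    cols = [f.id for f in feats]
    mat = np.log10(1.0 + dm.normalized.loc[cols].T)
    if sample_order is not None:
        mat = mat.loc[list(sample_order)]
    if path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(max(4, 0.25 * len(cols)),
                                        max(3, 0.3 * len(mat.index))))
        im = ax.imshow(mat.values, aspect="auto", cmap="viridis")
        ax.set_xticks(range(len(cols)), cols, rotation=90, fontsize=5)
        ax.set_yticks(range(len(mat.index)), mat.index, fontsize=6)
        fig.colorbar(im, ax=ax, label="log10(1 + normalized reads)")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return mat


def simulate_target_detection(
    genome: GenomeRecord,
    features: Sequence[GeneFeature],
    abundance: float,
    seed: int,
    depth: float = MEAN_SEQUENCING_DEPTH,
    read_length: int = 91,
    index: ReferenceIndex | None = None,
) -> pd.Series:
    """Normalized per-CDS counts for one species in one simulated metagenome.

    Only the target species' share of the sequencing depth is simulated
    (``depth * abundance% / read_length`` reads) since reads from other
    community members do not map to the target CDSs at error rate 0.  The
    sample depth is the full metagenome depth, and the mean depth is set
    equal to it, so the normalization factor is 1 and normalized counts
    equal raw counts.
    """
    from .synth import SimulationConfig, simulate_reads

    profile = CommunityProfile({genome.species: 100.0})
    cfg = SimulationConfig(seed=seed, depth_bases=depth * abundance / 100.0,
                           read_length=read_length)
    rs = simulate_reads([genome], profile, cfg, sample_id="sim")
    mc = map_reads(rs, features, [genome], index=index,
                   sample_depths={"sim": depth}, mean_depth=depth)
    dm = normalize_counts(mc)
    return dm.normalized["sim"]


# --------------------------------------------------------------------------
# contig species assignment


@dataclass
class ContigAnnotation:
    contig_id: str
    cds_list: list[tuple[str, str, float]]  # (cds_id, best_hit_species, identity %)
    assigned_species: str | None = None


def assign_contig_species(
    contig: ContigAnnotation,
    identity_threshold: float = 90.0,
    fraction: float = 0.5,
) -> str | None:
    """Assign a contig to a species by its CDS best hits.

    The contig is assigned iff at least ``fraction`` of its CDSs have best
    hits at >= ``identity_threshold`` percent identity, and those qualifying
    hits all point to a single species.  Qualifying hits split across more
    than one species, or too few of them, yield no assignment.
    """
    if not contig.cds_list:
        raise ValueError(f"contig {contig.contig_id!r} has an empty CDS list")
    qualifying = [(cds, sp) for cds, sp, ident in contig.cds_list
                  if ident >= identity_threshold]
    species = {sp for _, sp in qualifying}
    if len(species) == 1 and len(qualifying) >= fraction * len(contig.cds_list):
        assigned = species.pop()
    else:
        assigned = None
    contig.assigned_species = assigned
    return assigned


def pairwise_protein_identity(a, b) -> float:
    """Percent identity under global alignment (match 1, mismatch 0, gap -1).

    Identity is identical columns over total alignment columns, times 100.
    The gap penalty only shapes the traceback; it does not enter the
    identity value.  Accepts :class:`~flagmet.seqio.ProteinRecord` or plain
    strings.
    """
    from Bio import Align

    seq_a = getattr(a, "sequence", a)
    seq_b = getattr(b, "sequence", b)
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    alignment = aligner.align(seq_a, seq_b)[0]
    counts = alignment.counts()
    return 100.0 * counts.identities / alignment.length
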