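"""Synthetic genomes, transcripts, counts and miRNAs with planted ground truth.

The generator emulates the inputs of the lncRNA discovery pipeline for a
salt time course (conditions H0/H6/H12/H24, three replicates each):

* coding genes whose CDS is drawn from a biased codon-usage table, so that
  in-frame hexamer bias and Fickett-style position asymmetry are real
  signals and not artifacts;
* planted antisense lncRNAs (inside one gene, opposite strand) and
  intergenic lncRNAs (overlapping no gene), with noncoding sequence
  composition and no ORF longer than 300 nt;
* junk transcripts each violating exactly one basic filter;
* negative-binomial counts whose condition means follow one of six
  temporal archetypes (M1..M6);
* planted cis lncRNA-gene pairs with recorded side and boundary distance;
* miRNAs with planted complementary sites at controlled mismatch and
  G:U-wobble counts, plus decoy sites with >= 3 mismatches.

All randomness derives from one seed; each stage draws from its own
named stream, so adding a stage never perturbs earlier stages.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from intervaltree import IntervalTree

from saltlnc import io_formats
from saltlnc.io_formats import GeneRecord, GenomeAnnotation, TranscriptModel
from saltlnc.lncrna_filter import find_longest_orf

CONDITIONS = ("H0", "H6", "H12", "H24")

#: canonical temporal archetypes: condition-mean multipliers over H0,H6,H12,H24
ARCHETYPE_MULTIPLIERS: dict[str, tuple[float, float, float, float]] = {
    "M1": (1, 2, 4, 8),      # gradually induced from 0 h to 24 h
    "M2": (1, 6, 6, 2),      # rapidly induced at 6-12 h, declined at 24 h
    "M3": (8, 6, 2, 1),      # highest at 0 h
    "M4": (4, 8, 2, 1),      # highest at 6 h
    "M5": (8, 3, 2, 0.5),    # repressed; stays low at 24 h
    "M6": (8, 3, 2, 2),      # repressed; partial hold at 24 h
}

FUNCTIONAL_CATEGORIES = (
    "amino acid metabolism",
    "major CHO metabolism",
    "abiotic stress",
    "nitrate metabolism",
    "cell wall",
    "cell cycle",
    "hormone metabolism",
    "photosynthesis",
    "RNA transcription",
    "secondary metabolism",
    "transport",
)

#: category each archetype's co-expressed genes are preferentially drawn from
ARCHETYPE_SIGNATURE_CATEGORY = {
    "M1": "amino acid metabolism",
    "M2": "major CHO metabolism",
    "M3": "abiotic stress",
    "M4": "nitrate metabolism",
    "M5": "cell wall",
    "M6": "cell cycle",
}

JUNK_REASONS = ("length", "coverage", "recurrence", "orf_length", "same_strand_overlap")

_BASES = np.array(list("ACGT"))
_NONCODING_P = (0.32, 0.18, 0.18, 0.32)  # AT-rich intergenic composition
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimulationConfig:
    """All knobs of the generator; the seed fixes every downstream draw."""

    seed: int = 1
    n_chromosomes: int = 2
    chromosome_length: int = 7_000_000
    n_coding_genes: int = 2_000
    n_antisense: int = 15
    n_intergenic: int = 25
    n_junk: int = 10
    n_de_lncrnas: int = 24
    n_de_genes: int = 48
    n_cis_pairs: int = 6
    nb_dispersion: float = 0.05
    baseline_mean: float = 500.0
    baseline_sigma: float = 1.0
    library_size_sigma: float = 0.1
    n_replicates: int = 3
    window_up: int = 10_000
    window_down: int = 100_000
    n_mirnas: int = 8
    mirna_length: int = 21
    n_mirna_sites: int = 10
    n_decoy_sites: int = 5
    single_exon_fraction: float = 0.84
    lncrna_len_median: float = 430.0
    lncrna_len_sigma: float = 0.45
    enrichment_bias: float = 0.7
    archetype_multipliers: dict = field(
        default_factory=lambda: {k: tuple(v) for k, v in ARCHETYPE_MULTIPLIERS.items()}
    )

    def validate(self) -> None:
        if self.nb_dispersion < 0:
            raise ValueError("NB dispersion must be >= 0")
        for name, mult in self.archetype_multipliers.items():
            if len(mult) != len(CONDITIONS) or any(m <= 0 for m in mult):
                raise ValueError(f"archetype {name}: need {len(CONDITIONS)} positive multipliers")
        if self.n_antisense > self.n_coding_genes:
            raise ValueError("cannot plant more antisense lncRNAs than genes")
        if self.n_cis_pairs > min(self.n_intergenic, self.n_de_genes):
            raise ValueError("not enough intergenic lncRNAs or DE genes for cis pairs")
        for attr in ("n_chromosomes", "chromosome_length", "n_coding_genes", "n_replicates"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")


@dataclass
class GroundTruth:
    """Planted truth manifest for one synthetic dataset."""

    lncrna_classes: dict[str, str] = field(default_factory=dict)
    antisense_host: dict[str, str] = field(default_factory=dict)
    coding_ids: list[str] = field(default_factory=list)
    junk_reasons: dict[str, str] = field(default_factory=dict)
    de_archetype: dict[str, str] = field(default_factory=dict)
    de_log2fc: dict[str, dict[str, float]] = field(default_factory=dict)
    cis_pairs: list[dict] = field(default_factory=list)
    mirna_sites: list[dict] = field(default_factory=list)

    @property
    def lncrna_ids(self) -> list[str]:
        return list(self.lncrna_classes)

    @property
    def junk_ids(self) -> list[str]:
        return list(self.junk_reasons)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome: dict[str, str]
    annotation: GenomeAnnotation
    transcripts: list[TranscriptModel]
    counts: pd.DataFrame
    conditions: dict[str, str]
    size_factors: dict[str, float]
    mirnas: dict[str, str]
    truth: GroundTruth

    def transcript(self, tid: str) -> TranscriptModel:
        return next(t for t in self.transcripts if t.id == tid)

    def lengths(self) -> pd.Series:
        return pd.Series({t.id: t.spliced_length for t in self.transcripts})

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "genome.fa", "w") as fh:
            for name, seq in self.genome.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        io_formats.write_annotation(self.annotation, outdir / "genes.gff3")
        io_formats.write_transcripts(
            self.transcripts,
            outdir / "transcripts.gtf",
            outdir / "transcripts.fa",
            outdir / "sidecar.tsv",
        )
        io_formats.write_counts(self.counts, outdir / "counts.tsv")
        with open(outdir / "mirnas.fa", "w") as fh:
            for mid, seq in self.mirnas.items():
                fh.write(f">{mid}\n{seq.replace('T', 'U')}\n")
        with open(outdir / "design.tsv", "w") as fh:
            fh.write("sample_id\tcondition\n")
            for sample, cond in self.conditions.items():
                fh.write(f"{sample}\t{cond}\n")
        self.truth.to_json(outdir / "truth.json")


# ---------------------------------------------------------------------------
# RNG plumbing
# ---------------------------------------------------------------------------

def _rng(seed: int, stage: str) -> np.random.Generator:
    """One independent stream per (seed, stage-name)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(stage.encode())])
    )


def nb_sample(rng: np.random.Generator, mean, alpha: float, size=None) -> np.ndarray:
    """Negative-binomial draw with var = mean + alpha * mean^2 (Poisson at alpha=0).

    Implemented as a gamma-Poisson mixture so non-integer shape parameters
    and the alpha -> 0 limit behave smoothly.
    """
    mean = np.asarray(mean, dtype=float)
    if alpha < 0:
        raise ValueError("dispersion must be >= 0")
    if alpha < 1e-12:
        return rng.poisson(mean, size=size)
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mean, size=size)
    return rng.poisson(lam)


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, n: int, p=_NONCODING_P) -> str:
    return _BASE_BYTES[rng.choice(4, size=n, p=p)].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# codon usage
# ---------------------------------------------------------------------------

def _codon_usage_weights() -> tuple[list[str], np.ndarray]:
    """Sense codons with a fixed biased usage (one strongly preferred codon
    per amino acid), giving generated CDS a real hexamer/codon signal."""
    table = CodonTable.unambiguous_dna_by_id[1]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in sorted(table.forward_table.items()):
        by_aa.setdefault(aa, []).append(codon)
    codons, weights = [], []
    for aa, group in sorted(by_aa.items()):
        for i, codon in enumerate(group):
            codons.append(codon)
            weights.append(6.0 if i == 0 else 1.0)
    w = np.array(weights)
    return codons, w / w.sum()


_SENSE_CODONS, _CODON_P = _codon_usage_weights()
_STOP_CODONS = ("TAA", "TAG", "TGA")


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + biased sense codons + stop; stop-free in frame by construction."""
    body = "".join(rng.choice(_SENSE_CODONS, size=n_codons, p=_CODON_P))
    stop = _STOP_CODONS[rng.integers(3)]
    return "ATG" + body + stop


def _break_long_orfs(seq: str, max_orf: int = 300) -> str:
    """Inject in-frame stop codons until no ORF exceeds max_orf nt."""
    seq = list(seq)
    for _ in range(100):
        orf = find_longest_orf("".join(seq))
        if orf.length <= max_orf:
            return "".join(seq)
        mid = orf.start + 3 * ((orf.length // 3) // 2)
        seq[mid : mid + 3] = "TAA"
    raise RuntimeError("could not suppress long ORFs")


def _noncoding_seq(rng: np.random.Generator, n: int, max_orf: int = 300) -> str:
    return _break_long_orfs(_random_seq(rng, n), max_orf)


# ---------------------------------------------------------------------------
# stage 1: genome
# ---------------------------------------------------------------------------

def generate_genome(config: SimulationConfig) -> tuple[dict[str, str], GenomeAnnotation]:
    """Random chromosomes with non-overlapping codon-biased coding genes."""
    config.validate()
    rng = _rng(config.seed, "genome")
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_arrays = {
        name: _BASE_BYTES[
            rng.choice(4, size=config.chromosome_length, p=_NONCODING_P)
        ].copy()
        for name in chrom_names
    }

    genes: list[GeneRecord] = []
    cursors = {name: 0 for name in chrom_names}
    for i in range(config.n_coding_genes):
        chrom = chrom_names[i % len(chrom_names)]
        gap = int(rng.integers(2_000, 8_000))
        n_codons = int(rng.integers(100, 450))
        cds = random_cds(rng, n_codons)
        start = cursors[chrom] + gap
        end = start + len(cds)
        if end > config.chromosome_length:
            raise ValueError(
                "genes cannot be placed without overlap at the requested density; "
                "increase chromosome_length or reduce n_coding_genes"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        placed = cds if strand == "+" else revcomp(cds)
        chrom_arrays[chrom][start:end] = np.frombuffer(placed.encode("ascii"), dtype=np.uint8)
        genes.append(
            GeneRecord(
                id=f"SpG{i:05d}", chrom=chrom, strand=strand, start=start, end=end,
                functional_category=str(rng.choice(FUNCTIONAL_CATEGORIES)),
            )
        )
        cursors[chrom] = end

    genome = {name: arr.tobytes().decode("ascii") for name, arr in chrom_arrays.items()}
    annotation = GenomeAnnotation(
        chromosomes=[(name, config.chromosome_length) for name in chrom_names],
        genes=genes,
    )
    return genome, annotation


# ---------------------------------------------------------------------------
# stage 2: transcripts + truth
# ---------------------------------------------------------------------------

def _lncrna_length(config: SimulationConfig, rng: np.random.Generator) -> int:
    ln = rng.lognormal(np.log(config.lncrna_len_median), config.lncrna_len_sigma)
    return int(np.clip(ln, 200, 1_500))


def _make_exons(
    rng: np.random.Generator,
    config: SimulationConfig,
    region_start: int,
    region_end: int,
    spliced_len: int,
) -> list[tuple[int, int]] | None:
    """Exon chain of total length spliced_len inside [region_start, region_end).

    ~84% of lncRNAs are single-exon; multi-exon structures fall back to a
    single exon when the region cannot hold the introns.
    """
    room = region_end - region_start
    if room < spliced_len:
        return None
    multi = rng.random() > config.single_exon_fraction
    if multi:
        k = int(rng.integers(2, 5))
        if spliced_len >= 50 * k:
            cuts = np.sort(rng.choice(np.arange(50, spliced_len - 49), size=k - 1, replace=False))
            pieces = np.diff(np.concatenate([[0], cuts, [spliced_len]])).astype(int)
            introns = rng.integers(50, 150, size=k - 1)
            genomic = spliced_len + int(introns.sum())
            if genomic <= room and np.all(pieces >= 30):
                start = region_start + int(rng.integers(0, room - genomic + 1))
                exons, pos = [], start
                for j, piece in enumerate(pieces):
                    exons.append((pos, pos + int(piece)))
                    pos += int(piece)
                    if j < k - 1:
                        pos += int(introns[j])
                return exons
    start = region_start + int(rng.integers(0, room - spliced_len + 1))
    return [(start, start + spliced_len)]


def _place_free(
    rng: np.random.Generator,
    config: SimulationConfig,
    occupied: dict[str, IntervalTree],
    length: int,
    max_tries: int = 500,
) -> tuple[str, int] | None:
    """Random (chrom, start) whose [start-1, start+length+1) hits nothing."""
    chroms = sorted(occupied)
    for _ in range(max_tries):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(1, config.chromosome_length - length - 1))
        if not occupied[chrom].overlap(start - 1, start + length + 1):
            return chrom, start
    return None


def generate_transcripts(
    config: SimulationConfig,
    genome: dict[str, str],
    annotation: GenomeAnnotation,
) -> tuple[list[TranscriptModel], GroundTruth]:
    """Plant coding, antisense, intergenic, cis-paired and junk transcripts.

    Also assigns DE status, archetypes and (category-biased) functional
    categories; DE gene categories in ``annotation`` are updated in place
    so that each archetype's module is genuinely enriched for its
    signature category.
    """
    rng = _rng(config.seed, "transcripts")
    truth = GroundTruth()
    transcripts: list[TranscriptModel] = []

    occupied: dict[str, IntervalTree] = {name: IntervalTree() for name, _ in annotation.chromosomes}
    for g in annotation.genes:
        occupied[g.chrom].addi(g.start, g.end, g.id)

    # -- coding transcripts: one per gene, the CDS itself ------------------
    for g in annotation.genes:
        region = genome[g.chrom][g.start : g.end]
        seq = region if g.strand == "+" else revcomp(region)
        tid = f"TCONS_C{len(truth.coding_ids):05d}"
        transcripts.append(
            TranscriptModel(
                id=tid, chrom=g.chrom, strand=g.strand,
                exons=[(g.start, g.end)], sequence=seq,
                coverage=float(np.round(rng.uniform(5, 50), 2)),
                samples_detected=12,
            )
        )
        truth.coding_ids.append(tid)
    coding_by_gene = dict(zip([g.id for g in annotation.genes], truth.coding_ids))

    # -- DE gene selection (cis-pair genes are drawn from these) -----------
    archetype_names = sorted(config.archetype_multipliers)
    gene_order = rng.permutation(len(annotation.genes))
    de_gene_idx = list(gene_order[: config.n_de_genes])
    for j, gi in enumerate(de_gene_idx):
        tid = truth.coding_ids[gi]
        truth.de_archetype[tid] = archetype_names[j % len(archetype_names)]

    # -- antisense lncRNAs: inside one host gene, opposite strand ----------
    host_idx = rng.permutation(len(annotation.genes))[: config.n_antisense]
    n_lnc = 0
    for gi in host_idx:
        host = annotation.genes[gi]
        span = host.end - host.start
        length = min(_lncrna_length(config, rng), span)
        exons = _make_exons(rng, config, host.start, host.end, length)
        tid = f"TCONS_A{n_lnc:05d}"
        transcripts.append(
            TranscriptModel(
                id=tid, chrom=host.chrom, strand="-" if host.strand == "+" else "+",
                exons=exons, sequence=_noncoding_seq(rng, length),
                coverage=float(np.round(rng.uniform(3, 30), 2)),
                samples_detected=int(rng.integers(2, 13)),
            )
        )
        truth.lncrna_classes[tid] = "antisense"
        truth.antisense_host[tid] = host.id
        n_lnc += 1

    # -- cis-paired intergenic lncRNAs: controlled gap to a DE gene --------
    genes_by_id = {g.id: g for g in annotation.genes}
    cis_gene_ids = [annotation.genes[gi].id for gi in de_gene_idx[: config.n_cis_pairs]]
    n_intergenic_placed = 0
    for gene_id in cis_gene_ids:
        gene = genes_by_id[gene_id]
        placed = False
        for _ in range(200):
            length = _lncrna_length(config, rng)
            side = "upstream" if rng.random() < 0.5 else "downstream"
            gap = int(rng.integers(50, 1_500))
            lnc_strand = "+" if rng.random() < 0.5 else "-"
            # side is relative to the lncRNA's strand: its 5' side is
            # upstream, its 3' side downstream; genomic left/right follow.
            gene_left_of_lnc = (side == "upstream") == (lnc_strand == "+")
            if gene_left_of_lnc:
                start = gene.end + gap
            else:
                start = gene.start - gap - length
            if start < 1 or start + length + 1 > config.chromosome_length:
                continue
            if occupied[gene.chrom].overlap(start - 1, start + length + 1):
                continue
            tid = f"TCONS_I{n_intergenic_placed:05d}"
            transcripts.append(
                TranscriptModel(
                    id=tid, chrom=gene.chrom, strand=lnc_strand,
                    exons=[(start, start + length)],
                    sequence=_noncoding_seq(rng, length),
                    coverage=float(np.round(rng.uniform(3, 30), 2)),
                    samples_detected=int(rng.integers(2, 13)),
                )
            )
            occupied[gene.chrom].addi(start, start + length, tid)
            truth.lncrna_classes[tid] = "intergenic"
            truth.cis_pairs.append(
                {"lncrna_id": tid, "gene_id": gene.id, "side": side, "distance": gap}
            )
            n_intergenic_placed += 1
            placed = True
            break
        if not placed:
            raise RuntimeError("could not place cis-paired lncRNA; enlarge genome")

    # -- remaining intergenic lncRNAs --------------------------------------
    while n_intergenic_placed < config.n_intergenic:
        length = _lncrna_length(config, rng)
        loc = _place_free(rng, config, occupied, length)
        if loc is None:
            raise RuntimeError("no intergenic space left; enlarge genome")
        chrom, start = loc
        exons = _make_exons(rng, config, start, start + length + 600, length) or [
            (start, start + length)
        ]
        if occupied[chrom].overlap(exons[0][0] - 1, exons[-1][1] + 1):
            exons = [(start, start + length)]
        tid = f"TCONS_I{n_intergenic_placed:05d}"
        transcripts.append(
            TranscriptModel(
                id=tid, chrom=chrom, strand="+" if rng.random() < 0.5 else "-",
                exons=exons, sequence=_noncoding_seq(rng, length),
                coverage=float(np.round(rng.uniform(3, 30), 2)),
                samples_detected=int(rng.integers(2, 13)),
            )
        )
        occupied[chrom].addi(exons[0][0], exons[-1][1], tid)
        truth.lncrna_classes[tid] = "intergenic"
        n_intergenic_placed += 1

    # -- DE lncRNAs: cis lncRNAs share their gene's archetype --------------
    for pair in truth.cis_pairs:
        truth.de_archetype[pair["lncrna_id"]] = truth.de_archetype[
            coding_by_gene[pair["gene_id"]]
        ]
    other_lnc = [t for t in truth.lncrna_ids if t not in truth.de_archetype]
    extra = rng.permutation(len(other_lnc))[: max(0, config.n_de_lncrnas - config.n_cis_pairs)]
    for j, li in enumerate(extra):
        truth.de_archetype[other_lnc[li]] = archetype_names[j % len(archetype_names)]

    # true per-comparison log2 fold changes from the multiplier table
    comparisons = [
        (a, b) for i, a in enumerate(CONDITIONS) for b in CONDITIONS[i + 1 :]
    ]
    for tid, arch in truth.de_archetype.items():
        mult = dict(zip(CONDITIONS, config.archetype_multipliers[arch]))
        truth.de_log2fc[tid] = {
            f"{a}_{b}": float(np.log2(mult[b] / mult[a])) for a, b in comparisons
        }

    # -- category bias: DE genes lean toward their archetype's signature ---
    new_genes = []
    for gi, g in enumerate(annotation.genes):
        tid = truth.coding_ids[gi]
        if tid in truth.de_archetype and rng.random() < config.enrichment_bias:
            cat = ARCHETYPE_SIGNATURE_CATEGORY.get(
                truth.de_archetype[tid], g.functional_category
            )
            g = dataclasses.replace(g, functional_category=cat)
        new_genes.append(g)
    annotation.genes = new_genes

    # -- junk transcripts: exactly one violated filter each ----------------
    non_host_genes = [
        g for g in annotation.genes if g.id not in set(truth.antisense_host.values())
    ]
    for j in range(config.n_junk):
        reason = JUNK_REASONS[j % len(JUNK_REASONS)]
        tid = f"TCONS_J{j:05d}"
        length = _lncrna_length(config, rng)
        coverage = float(np.round(rng.uniform(3, 30), 2))
        samples = int(rng.integers(2, 13))
        if reason == "length":
            length = int(rng.integers(150, 200))
        elif reason == "coverage":
            coverage = float(np.round(rng.uniform(0.2, 2.9), 2))
        elif reason == "recurrence":
            samples = 1
        if reason == "same_strand_overlap":
            host = non_host_genes[j % len(non_host_genes)]
            length = min(length, host.end - host.start)
            start = host.start + int(rng.integers(0, host.end - host.start - length + 1))
            chrom, strand = host.chrom, host.strand
            seq = _noncoding_seq(rng, length)
        else:
            if reason == "orf_length":
                n_codons = int(rng.integers(110, 130))
                orf = random_cds(rng, n_codons)
                seq = _noncoding_seq(rng, 60) + orf + _noncoding_seq(rng, 60)
                length = len(seq)
            else:
                seq = _noncoding_seq(rng, length)
            loc = _place_free(rng, config, occupied, length)
            if loc is None:
                raise RuntimeError("no space for junk transcript; enlarge genome")
            chrom, start = loc
            strand = "+" if rng.random() < 0.5 else "-"
        transcripts.append(
            TranscriptModel(
                id=tid, chrom=chrom, strand=strand,
                exons=[(start, start + length)], sequence=seq,
                coverage=coverage, samples_detected=samples,
            )
        )
        if reason != "same_strand_overlap":
            occupied[chrom].addi(start, start + length, tid)
        truth.junk_reasons[tid] = reason

    return transcripts, truth


# ---------------------------------------------------------------------------
# stage 3: counts
# ---------------------------------------------------------------------------

def sample_names(n_replicates: int = 3) -> list[str]:
    return [f"{c}_r{r + 1}" for c in CONDITIONS for r in range(n_replicates)]


def generate_counts(
    config: SimulationConfig,
    truth: GroundTruth,
) -> tuple[pd.DataFrame, dict[str, str], dict[str, float]]:
    """NB counts: k_ij ~ NB(mean = s_j * q_i * m_{a(i), c(j)}, dispersion alpha).

    Non-DE features use multiplier 1 at every condition.  Returns the
    matrix, the sample -> condition map, and the true library-size factors.
    """
    rng = _rng(config.seed, "counts")
    features = truth.coding_ids + truth.lncrna_ids + truth.junk_ids
    samples = sample_names(config.n_replicates)
    conditions = {s: s.split("_")[0] for s in samples}

    s_j = np.exp(rng.normal(0.0, config.library_size_sigma, size=len(samples)))
    s_j /= np.exp(np.mean(np.log(s_j)))  # geometric mean 1
    q_i = rng.lognormal(np.log(config.baseline_mean), config.baseline_sigma, size=len(features))

    mult = np.ones((len(features), len(samples)))
    cond_index = {c: i for i, c in enumerate(CONDITIONS)}
    for fi, fid in enumerate(features):
        arch = truth.de_archetype.get(fid)
        if arch is not None:
            m = config.archetype_multipliers[arch]
            for sj, s in enumerate(samples):
                mult[fi, sj] = m[cond_index[conditions[s]]]

    means = q_i[:, None] * s_j[None, :] * mult
    counts = nb_sample(rng, means, config.nb_dispersion)
    df = pd.DataFrame(counts, index=features, columns=samples, dtype=int)
    return df, conditions, dict(zip(samples, s_j))


def simulate_two_group(
    n_null: int,
    n_de: int,
    mean: float,
    log2fc: float,
    alpha: float,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Two-condition NB experiment with n_de features at the given fold change.

    DE feature ids start with ``de_``; all features share the baseline mean
    in group A.  Used for power and type-I-error studies of the exact test.
    """
    rng = _rng(seed, "two_group")
    ids = [f"null_{i}" for i in range(n_null)] + [f"de_{i}" for i in range(n_de)]
    group_a = [f"A_r{r + 1}" for r in range(n_replicates)]
    group_b = [f"B_r{r + 1}" for r in range(n_replicates)]
    mean_b = np.concatenate(
        [np.full(n_null, mean), np.full(n_de, mean * 2.0 ** log2fc)]
    )
    a = nb_sample(rng, np.full((len(ids), n_replicates), mean), alpha)
    b = nb_sample(rng, np.tile(mean_b[:, None], (1, n_replicates)), alpha)
    df = pd.DataFrame(
        np.hstack([a, b]), index=ids, columns=group_a + group_b, dtype=int
    )
    return df, group_a, group_b


# ---------------------------------------------------------------------------
# stage 4: miRNAs and planted sites
# ---------------------------------------------------------------------------

_WOBBLE_TARGET = {"G": "T", "T": "G"}  # miRNA base -> target base forming G:U


def _mutate_window(
    rng: np.random.Generator, mirna: str, n_mismatch: int, n_wobble: int
) -> str | None:
    """Target window pairing with the miRNA at exactly the requested counts.

    Starts from the exact reverse complement and edits distinct positions:
    a wobble needs the miRNA base to be G or T; a mismatch replaces the
    target base by one that is neither the Watson-Crick partner nor the
    wobble partner.
    """
    L = len(mirna)
    window = list(revcomp(mirna))
    wobble_ok = [k for k, b in enumerate(mirna) if b in _WOBBLE_TARGET]
    if len(wobble_ok) < n_wobble:
        return None
    positions = list(range(L))
    wob = sorted(rng.choice(wobble_ok, size=n_wobble, replace=False)) if n_wobble else []
    rest = [k for k in positions if k not in wob]
    mis = sorted(rng.choice(rest, size=n_mismatch, replace=False)) if n_mismatch else []
    for k in wob:
        window[L - 1 - k] = _WOBBLE_TARGET[mirna[k]]
    for k in mis:
        wc = revcomp(mirna[k])
        banned = {wc, _WOBBLE_TARGET.get(mirna[k], "")}
        choices = [b for b in "ACGT" if b not in banned]
        window[L - 1 - k] = choices[int(rng.integers(len(choices)))]
    return "".join(window)


_MIRNA_FAMILY_NUMBERS = (156, 159, 166, 169, 171, 319, 393, 397, 398, 399, 408, 827)


def generate_mirnas(
    config: SimulationConfig,
    truth: GroundTruth,
    transcripts: list[TranscriptModel],
) -> dict[str, str]:
    """Random mature miRNAs; plant complementary sites into DE lncRNAs.

    Accepted-site plants cycle through mismatch/wobble combinations within
    the (<=2 mismatch, <=4 wobble) rule; decoys carry >= 3 mismatches.
    Edited transcripts are re-checked so no ORF longer than 300 nt appears.
    Sequences are DNA-alphabet internally (T == U).
    """
    rng = _rng(config.seed, "mirnas")
    mirnas: dict[str, str] = {}
    for i in range(config.n_mirnas):
        fam = _MIRNA_FAMILY_NUMBERS[i % len(_MIRNA_FAMILY_NUMBERS)]
        letter = "abcdef"[i // len(_MIRNA_FAMILY_NUMBERS)]
        mid = f"miR{fam}{letter}-5p"
        mirnas[mid] = _random_seq(rng, config.mirna_length, p=(0.25,) * 4)

    by_id = {t.id: t for t in transcripts}
    de_lnc = [t for t in truth.lncrna_ids if t in truth.de_archetype]
    if not de_lnc:
        return mirnas
    combos = [(0, 0), (1, 0), (2, 0), (1, 1), (0, 2), (2, 2), (2, 4)]
    decoy_mm = (3, 4, 5)
    used: dict[str, list[tuple[int, int]]] = {}
    mirna_ids = list(mirnas)

    def plant(site_no: int, n_mismatch: int, n_wobble: int) -> None:
        mid = mirna_ids[site_no % len(mirna_ids)]
        mseq = mirnas[mid]
        L = len(mseq)
        for _ in range(100):
            tid = de_lnc[int(rng.integers(len(de_lnc)))]
            t = by_id[tid]
            if t.spliced_length < L + 2:
                continue
            offset = int(rng.integers(0, t.spliced_length - L + 1))
            if any(offset < e and offset + L > s for s, e in used.get(tid, [])):
                continue
            window = _mutate_window(rng, mseq, n_mismatch, n_wobble)
            if window is None:
                return
            new_seq = t.sequence[:offset] + window + t.sequence[offset + L :]
            if find_longest_orf(new_seq).length > 300:
                continue
            t.sequence = new_seq
            used.setdefault(tid, []).append((offset, offset + L))
            truth.mirna_sites.append(
                {
                    "mirna_id": mid, "transcript_id": tid, "offset": offset,
                    "n_mismatch": n_mismatch, "n_wobble": n_wobble,
                }
            )
            return
        raise RuntimeError("could not place miRNA site")

    for s in range(config.n_mirna_sites):
        mm, wb = combos[s % len(combos)]
        plant(s, mm, wb)
    for d in range(config.n_decoy_sites):
        plant(config.n_mirna_sites + d, decoy_mm[d % len(decoy_mm)], 0)
    return mirnas


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def generate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Full dataset: genome, annotation, transcripts, counts, miRNAs, truth."""
    config = config or SimulationConfig()
    genome, annotation = generate_genome(config)
    transcripts, truth = generate_transcripts(config, genome, annotation)
    counts, conditions, size_factors = generate_counts(config, truth)
    mirnas = generate_mirnas(config, truth, transcripts)
    return SyntheticDataset(
        config=config, genome=genome, annotation=annotation,
        transcripts=transcripts, counts=counts, conditions=conditions,
        size_factors=size_factors, mirnas=mirnas, truth=truth,
    )
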