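"""Generator contracts: determinism, planted-truth internal consistency,
count-model statistics."""

import dataclasses

import numpy as np
import pytest

from saltlnc import synthetic_data as sd
from saltlnc.synthetic_data import (
    ARCHETYPE_MULTIPLIERS,
    CONDITIONS,
    GroundTruth,
    SimulationConfig,
    generate_counts,
    generate_genome,
    nb_sample,
    revcomp,
)
from tests.conftest import SMALL_CONFIG_KWARGS

_STOPS = {"TAA", "TAG", "TGA"}


def _brute_longest_orf(seq):
    """Independent ORF oracle: every (ATG, next in-frame stop) pair."""
    best = 0
    n = len(seq)
    for i in range(n - 2):
        if seq[i : i + 3] != "ATG":
            continue
        for j in range(i + 3, n - 2, 3):
            if seq[j : j + 3] in _STOPS:
                best = max(best, j + 3 - i)
                break
    return best


class TestDeterminism:
    def test_same_seed_gives_identical_datasets(self):
        cfg = SimulationConfig(seed=11, **SMALL_CONFIG_KWARGS)
        a = sd.generate_dataset(cfg)
        b = sd.generate_dataset(dataclasses.replace(cfg))
        assert a.genome == b.genome
        assert a.annotation.genes == b.annotation.genes
        assert sorted(a.transcripts, key=lambda t: t.id) == sorted(
            b.transcripts, key=lambda t: t.id
        )
        assert a.counts.equals(b.counts)
        assert a.mirnas == b.mirnas
        assert dataclasses.asdict(a.truth) == dataclasses.asdict(b.truth)

    def test_different_seeds_differ(self):
        cfg = SimulationConfig(seed=11, **SMALL_CONFIG_KWARGS)
        a = sd.generate_dataset(cfg)
        b = sd.generate_dataset(dataclasses.replace(cfg, seed=12))
        assert not a.counts.equals(b.counts)


class TestGenome:
    def test_requested_gene_count(self):
        cfg = SimulationConfig(seed=3, n_coding_genes=50, chromosome_length=600_000)
        _, ann = generate_genome(cfg)
        assert len(ann.genes) == 50

    def test_cds_start_stop_and_no_internal_stops(self):
        cfg = SimulationConfig(seed=4, n_coding_genes=50, chromosome_length=600_000)
        genome, ann = generate_genome(cfg)
        for g in ann.genes:
            region = genome[g.chrom][g.start : g.end]
            cds = region if g.strand == "+" else revcomp(region)
            assert cds[:3] == "ATG"
            assert cds[-3:] in _STOPS
            internal = {cds[i : i + 3] for i in range(3, len(cds) - 3, 3)}
            assert not (internal & _STOPS)

    def test_overcrowded_genome_raises(self):
        cfg = SimulationConfig(seed=5, n_coding_genes=200, chromosome_length=50_000)
        with pytest.raises(ValueError, match="density"):
            generate_genome(cfg)


class TestPlantedTruth:
    def test_truth_id_sets_are_disjoint(self, small_dataset):
        t = small_dataset.truth
        sets = [set(t.lncrna_ids), set(t.coding_ids), set(t.junk_ids)]
        for i in range(3):
            for j in range(i + 1, 3):
                assert not (sets[i] & sets[j])

    def test_intergenic_lncrnas_overlap_no_gene(self, small_dataset):
        """Interval oracle over every gene span, both strands."""
        spans = [(g.chrom, g.start, g.end) for g in small_dataset.annotation.genes]
        by_id = {t.id: t for t in small_dataset.transcripts}
        for tid, cls in small_dataset.truth.lncrna_classes.items():
            if cls != "intergenic":
                continue
            t = by_id[tid]
            hits = [
                1 for chrom, s, e in spans
                if chrom == t.chrom and s < t.end and e > t.start
            ]
            assert not hits, f"{tid} overlaps a gene"

    def test_antisense_lncrnas_overlap_exactly_their_host_oppositely(self, small_dataset):
        genes = {g.id: g for g in small_dataset.annotation.genes}
        by_id = {t.id: t for t in small_dataset.transcripts}
        for tid, host_id in small_dataset.truth.antisense_host.items():
            t, host = by_id[tid], genes[host_id]
            assert t.chrom == host.chrom and t.strand != host.strand
            assert t.start < host.end and t.end > host.start
            others = [
                g for g in small_dataset.annotation.genes
                if g.id != host_id and g.chrom == t.chrom
                and g.start < t.end and g.end > t.start
            ]
            assert not others

    def test_junk_transcripts_violate_exactly_their_named_filter(self, small_dataset):
        by_id = {t.id: t for t in small_dataset.transcripts}
        genes = small_dataset.annotation.genes
        for tid, reason in small_dataset.truth.junk_reasons.items():
            t = by_id[tid]
            violations = set()
            if t.spliced_length < 200:
                violations.add("length")
            if t.coverage < 3:
                violations.add("coverage")
            if t.samples_detected < 2:
                violations.add("recurrence")
            if _brute_longest_orf(t.sequence) > 300:
                violations.add("orf_length")
            if any(
                g.chrom == t.chrom and g.strand == t.strand
                and g.start < t.end and g.end > t.start
                for g in genes
            ):
                violations.add("same_strand_overlap")
            assert violations == {reason}, f"{tid}: {violations} != {{{reason}}}"

    def test_planted_lncrnas_pass_every_basic_filter(self, small_dataset):
        by_id = {t.id: t for t in small_dataset.transcripts}
        for tid in small_dataset.truth.lncrna_ids:
            t = by_id[tid]
            assert t.spliced_length >= 200
            assert t.coverage >= 3
            assert t.samples_detected >= 2
            assert _brute_longest_orf(t.sequence) <= 300

    def test_cis_distances_respect_their_windows(self, small_dataset):
        cfg = small_dataset.config
        for pair in small_dataset.truth.cis_pairs:
            window = cfg.window_up if pair["side"] == "upstream" else cfg.window_down
            assert 0 <= pair["distance"] <= window


class TestCounts:
    def test_counts_are_nonnegative_integers(self, small_dataset):
        counts = small_dataset.counts
        assert (counts.to_numpy() >= 0).all()
        assert counts.dtypes.map(lambda d: np.issubdtype(d, np.integer)).all()

    def test_poisson_limit_variance_over_mean(self):
        rng = np.random.default_rng(42)
        draws = nb_sample(rng, np.full(10_000, 1000.0), alpha=1e-14)
        ratio = draws.var(ddof=1) / draws.mean()
        assert abs(ratio - 1.0) < 0.05

    def test_dispersion_inflates_variance(self):
        rng = np.random.default_rng(42)
        draws = nb_sample(rng, np.full(10_000, 1000.0), alpha=0.05)
        # var = mu + alpha mu^2 = 1000 + 50_000
        assert draws.var(ddof=1) / draws.mean() > 20

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            nb_sample(np.random.default_rng(0), 10.0, alpha=-0.1)

    def test_m1_condition_means_are_increasing(self):
        """200 planted M1 features at baseline 1000: H0 < H6 < H12 < H24."""
        truth = GroundTruth(
            coding_ids=[f"f{i}" for i in range(200)],
            de_archetype={f"f{i}": "M1" for i in range(200)},
        )
        cfg = SimulationConfig(seed=8, baseline_mean=1000.0, baseline_sigma=1e-9,
                               library_size_sigma=0.0)
        counts, conditions, _ = generate_counts(cfg, truth)
        cond_means = {
            c: counts[[s for s, cc in conditions.items() if cc == c]].to_numpy().mean()
            for c in CONDITIONS
        }
        assert (
            cond_means["H0"] < cond_means["H6"] < cond_means["H12"] < cond_means["H24"]
        )


class TestMirnaSites:
    def test_planted_site_counts_match_independent_pairing_scan(self, small_dataset):
        """Brute-force per-position oracle re-derives every manifest entry."""
        wc = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
        wob = {("G", "T"), ("T", "G")}
        by_id = {t.id: t for t in small_dataset.transcripts}
        assert small_dataset.truth.mirna_sites, "no sites planted"
        for site in small_dataset.truth.mirna_sites:
            m = small_dataset.mirnas[site["mirna_id"]]
            t = by_id[site["transcript_id"]]
            L = len(m)
            window = t.sequence[site["offset"] : site["offset"] + L]
            mm = wb = 0
            for k in range(L):
                pair = (m[k], window[L - 1 - k])
                if pair in wc:
                    continue
                wb += pair in wob
                mm += pair not in wob
            assert (mm, wb) == (site["n_mismatch"], site["n_wobble"])

    def test_zero_edit_site_is_exact_reverse_complement(self, small_dataset):
        by_id = {t.id: t for t in small_dataset.transcripts}
        exact = [
            s for s in small_dataset.truth.mirna_sites
            if s["n_mismatch"] == 0 and s["n_wobble"] == 0
        ]
        assert exact
        for site in exact:
            m = small_dataset.mirnas[site["mirna_id"]]
            t = by_id[site["transcript_id"]]
            assert t.sequence[site["offset"] : site["offset"] + len(m)] == revcomp(m)


def test_written_dataset_reloads_consistently(tmp_path, small_dataset):
    """The emitted files alone reproduce the in-memory objects."""
    from saltlnc import io_formats as io

    small_dataset.write(tmp_path)
    ann = io.read_annotation(tmp_path / "genes.gff3")
    assert sorted(ann.genes, key=lambda g: g.id) == sorted(
        small_dataset.annotation.genes, key=lambda g: g.id
    )
    models = io.read_transcripts(
        tmp_path / "transcripts.gtf", tmp_path / "transcripts.fa", tmp_path / "sidecar.tsv"
    )
    assert models == sorted(small_dataset.transcripts, key=lambda t: t.id)
    counts = io.read_counts(tmp_path / "counts.tsv")
    assert counts.equals(small_dataset.counts)
    truth = GroundTruth.from_json(tmp_path / "truth.json")
    assert dataclasses.asdict(truth) == dataclasses.asdict(small_dataset.truth)
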