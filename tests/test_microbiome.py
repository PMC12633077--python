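"""Taxon tables, rank aggregation, Bray–Curtis, PERMANOVA, taxon rhythms."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rhythmkit import (
    CommunitySpec,
    InvalidArgumentError,
    TaxaTable,
    aggregate_rank,
    bray_curtis,
    load_taxa,
    permanova,
    relative_abundance,
    simulate_microbiome,
    taxa_rhythms,
    write_taxa,
)
from rhythmkit.microbiome import DistanceMatrix, permanova_exact


def _table(counts, lineages, groups=None, times=None):
    samples = list(counts.index)
    meta = pd.DataFrame(
        {
            "group": groups if groups is not None else ["wt"] * len(samples),
            "time_h": times if times is not None else [2.0] * len(samples),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return TaxaTable(counts=counts, taxonomy=lineages, metadata=meta, mode="counts")


@pytest.fixture
def small_table():
    counts = pd.DataFrame(
        [[5, 7, 1, 0], [2, 3, 4, 1], [0, 0, 10, 2]],
        index=["s1", "s2", "s3"],
        columns=["t1", "t2", "t3", "t4"],
    )
    lineages = {
        "t1": "Bacteria;Bacillota;Clostridia;Lachnospirales;Lachnospiraceae;Blautia",
        "t2": "Bacteria;Bacillota;Clostridia;Lachnospirales;Lachnospiraceae;Blautia",
        "t3": "Bacteria;Bacteroidota;Bacteroidia;Bacteroidales;Bacteroidaceae;Bacteroides",
        "t4": "Bacteria;Bacteroidota;Bacteroidia;Bacteroidales;Marinifilaceae;",
    }
    return _table(counts, lineages)


class TestLoadTaxa:
    def _write_files(self, tmp_path, table):
        paths = (tmp_path / "c.tsv", tmp_path / "x.tsv", tmp_path / "m.tsv")
        write_taxa(table, *paths)
        return paths

    def test_small_fixture_dimensions(self, tmp_path, small_table):
        loaded = load_taxa(*self._write_files(tmp_path, small_table))
        assert loaded.counts.shape == (3, 4)
        assert loaded.samples == ["s1", "s2", "s3"]

    def test_round_trip_preserves_counts(self, tmp_path, small_table):
        loaded = load_taxa(*self._write_files(tmp_path, small_table))
        pd.testing.assert_frame_equal(
            loaded.counts, small_table.counts, check_dtype=False
        )
        assert loaded.taxonomy == small_table.taxonomy

    def test_sample_without_metadata_hard_error(self, tmp_path, small_table):
        paths = self._write_files(tmp_path, small_table)
        meta = pd.read_csv(paths[2], sep="\t")
        meta = meta[meta["sample_id"] != "s2"]
        meta.to_csv(paths[2], sep="\t", index=False)
        with pytest.raises(InvalidArgumentError, match="s2"):
            load_taxa(*paths)


class TestAggregateRank:
    def test_same_genus_counts_add(self, small_table):
        agg = aggregate_rank(small_table, "genus")
        assert agg.counts.loc["s1", "Blautia"] == 12  # 5 + 7

    def test_missing_genus_bucketed_under_parent(self, small_table):
        agg = aggregate_rank(small_table, "genus")
        assert "unclassified_Marinifilaceae" in agg.taxa

    def test_finest_rank_with_distinct_genera_is_identity(self):
        counts = pd.DataFrame([[3, 4]], index=["s1"], columns=["a", "b"])
        lineages = {"a": "K;P;C;O;F;Ga", "b": "K;P;C;O;F;Gb"}
        agg = aggregate_rank(_table(counts, lineages), "genus")
        assert sorted(agg.taxa) == ["Ga", "Gb"]
        assert agg.counts.to_numpy().sum() == 7

    def test_total_count_conserved(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 100, size=(6, 10)),
            index=[f"s{i}" for i in range(6)],
            columns=[f"t{i}" for i in range(10)],
        )
        lineages = {
            f"t{i}": f"K;P{i % 2};C;O;F{i % 3};G{i % 4}" for i in range(10)
        }
        table = _table(counts, lineages)
        for rank in ("phylum", "family", "genus"):
            agg = aggregate_rank(table, rank)
            np.testing.assert_array_equal(
                agg.counts.sum(axis=1).to_numpy(), counts.sum(axis=1).to_numpy()
            )

    def test_unknown_rank_rejected(self, small_table):
        with pytest.raises(InvalidArgumentError):
            aggregate_rank(small_table, "strain")


class TestRelativeAbundance:
    def test_proportions(self):
        counts = pd.DataFrame([[2, 3, 5]], index=["s1"], columns=["a", "b", "c"])
        lineages = {t: "K;P;C;O;F;" + t for t in ("a", "b", "c")}
        props = relative_abundance(_table(counts, lineages))
        np.testing.assert_allclose(props.counts.loc["s1"], [0.2, 0.3, 0.5])
        assert props.mode == "proportions"

    def test_single_taxon_all_one(self):
        counts = pd.DataFrame([[9], [4]], index=["s1", "s2"], columns=["a"])
        props = relative_abundance(_table(counts, {"a": "K;P;C;O;F;a"}))
        np.testing.assert_allclose(props.counts.to_numpy(), 1.0)

    def test_inverse_reconstructs_counts(self, rng):
        counts = pd.DataFrame(
            rng.integers(1, 50, size=(4, 5)),
            index=[f"s{i}" for i in range(4)],
            columns=[f"t{i}" for i in range(5)],
        )
        lineages = {f"t{i}": f"K;P;C;O;F;G{i}" for i in range(5)}
        table = _table(counts, lineages)
        props = relative_abundance(table)
        reconstructed = props.counts.mul(counts.sum(axis=1), axis=0)
        np.testing.assert_allclose(reconstructed.to_numpy(), counts.to_numpy(), atol=1e-9)

    def test_zero_total_sample_named(self):
        counts = pd.DataFrame([[1, 2], [0, 0]], index=["s1", "s2"], columns=["a", "b"])
        lineages = {"a": "K;P;C;O;F;a", "b": "K;P;C;O;F;b"}
        with pytest.raises(InvalidArgumentError, match="s2"):
            relative_abundance(_table(counts, lineages))


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        counts = pd.DataFrame(
            [[3, 1, 0], [3, 1, 0], [0, 0, 5]],
            index=["s1", "s2", "s3"],
            columns=["a", "b", "c"],
        )
        lineages = {t: "K;P;C;O;F;" + t for t in ("a", "b", "c")}
        d = bray_curtis(_table(counts, lineages))
        assert d.matrix[0, 1] == pytest.approx(0.0)
        assert d.matrix[0, 2] == pytest.approx(1.0)

    def test_hand_evaluated_pair(self):
        counts = pd.DataFrame([[2, 1], [1, 1]], index=["u", "v"], columns=["a", "b"])
        lineages = {"a": "K;P;C;O;F;a", "b": "K;P;C;O;F;b"}
        d = bray_curtis(_table(counts, lineages))
        assert d.matrix[0, 1] == pytest.approx(0.2)  # |1|+|0| over 5

    def test_semimetric_properties_and_taxon_permutation(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 40, size=(5, 8)) + 1,
            index=[f"s{i}" for i in range(5)],
            columns=[f"t{i}" for i in range(8)],
        )
        lineages = {f"t{i}": f"K;P;C;O;F;G{i}" for i in range(8)}
        table = _table(counts, lineages)
        d = bray_curtis(table)
        m = d.matrix
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 0.0)
        assert m.min() >= 0.0 and m.max() <= 1.0
        perm = rng.permutation(8)
        shuffled = _table(counts.iloc[:, perm], lineages)
        np.testing.assert_allclose(bray_curtis(shuffled).matrix, m, atol=1e-12)

    def test_all_zero_sample_flagged(self):
        counts = pd.DataFrame([[0, 0], [0, 0]], index=["s1", "s2"], columns=["a", "b"])
        lineages = {"a": "K;P;C;O;F;a", "b": "K;P;C;O;F;b"}
        with pytest.raises(InvalidArgumentError):
            bray_curtis(_table(counts, lineages))


def _random_distance(rng, n):
    pts = rng.uniform(0.05, 1.0, size=(n, 4))
    pts /= pts.sum(axis=1, keepdims=True)
    from scipy.spatial.distance import pdist, squareform

    return DistanceMatrix(
        matrix=squareform(pdist(pts, "braycurtis")),
        ids=tuple(f"s{i}" for i in range(n)),
    )


class TestPermanova:
    def test_reproducible_from_seed(self, rng):
        d = _random_distance(rng, 12)
        labels = ["a"] * 6 + ["b"] * 6
        r1 = permanova(d, labels, n_perm=99, seed=42)
        r2 = permanova(d, labels, n_perm=99, seed=42)
        assert r1.p == r2.p and r1.statistic == r2.statistic

    def test_statistic_matches_skbio(self, rng):
        """Pseudo-F agrees with scikit-bio's PERMANOVA implementation."""
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        d = _random_distance(rng, 10)
        labels = ["a"] * 5 + ["b"] * 5
        ours = permanova(d, labels, n_perm=9, seed=0)
        ref = skbio_distance.permanova(
            skbio_distance.DistanceMatrix(d.matrix, ids=list(d.ids)),
            list(labels),
            permutations=99,
        )
        assert ours.statistic == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_null_p_uniform(self):
        """Labels independent of data: p approximately uniform over 500
        simulated datasets (KS at alpha = 0.01, discreteness smoothed)."""
        rng = np.random.default_rng(21)
        n_perm = 199
        ps = []
        for _ in range(500):
            d = _random_distance(rng, 12)
            labels = rng.permutation(["a"] * 6 + ["b"] * 6)
            ps.append(permanova(d, labels, n_perm=n_perm, seed=int(rng.integers(2**31))).p)
        # p takes values k/(1+n_perm): de-discretize before the KS check
        u = (np.asarray(ps) * (1 + n_perm) - rng.uniform(size=500)) / (1 + n_perm)
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_strong_effect_saturates(self):
        spec = CommunitySpec(
            taxa=("a", "b", "c"),
            baseline=(0.5, 0.3, 0.2),
            amplitude=(0.0, 0.0, 0.0),
            acrophase_h=(0.0, 0.0, 0.0),
            concentration=500.0,
            group_overrides={},
        )
        table = simulate_microbiome(spec, groups=("g1", "g2"), n_per_cell=3, seed=5)
        counts = table.counts.copy()
        g2 = table.metadata["group"] == "g2"
        # build a strong compositional shift between groups
        counts.loc[g2.to_numpy(), "a"] += counts.loc[g2.to_numpy()].sum(axis=1)
        shifted = TaxaTable(counts=counts, taxonomy=table.taxonomy,
                            metadata=table.metadata, mode="counts")
        d = bray_curtis(shifted)
        res = permanova(d, table.metadata["group"].to_numpy(), n_perm=999, seed=6)
        assert res.p == pytest.approx(1.0 / 1000.0)

    def test_matches_exhaustive_enumeration(self, rng):
        """3+3 design: the sampled permutation p converges to the exhaustive
        enumeration over all 20 assignments (+1-corrected)."""
        d = _random_distance(rng, 6)
        labels = np.array(["a"] * 3 + ["b"] * 3)
        f_obs, p_exact = permanova_exact(d, labels)
        res = permanova(d, labels, n_perm=49999, seed=7)
        assert res.statistic == pytest.approx(f_obs, rel=1e-12)
        # +1-corrected MC estimate of the same tail probability
        assert res.p == pytest.approx(p_exact, abs=0.01)

    def test_group_of_one_rejected(self, rng):
        d = _random_distance(rng, 5)
        with pytest.raises(InvalidArgumentError):
            permanova(d, ["a"] * 4 + ["b"], n_perm=9, seed=0)


def _flat_community(n_taxa=21, conc=300.0):
    baseline = tuple(np.full(n_taxa, 1.0 / n_taxa))
    return CommunitySpec(
        taxa=tuple(f"g{i:02d}" for i in range(n_taxa)),
        baseline=baseline,
        amplitude=tuple(np.zeros(n_taxa)),
        acrophase_h=tuple(np.zeros(n_taxa)),
        concentration=conc,
    )


class TestTaxaRhythms:
    def test_requires_proportions(self):
        table = simulate_microbiome(_flat_community(5), groups=("wt",), n_per_cell=4, seed=1)
        with pytest.raises(InvalidArgumentError):
            taxa_rhythms(table)

    def test_spike_in_oscillator_detected(self):
        """One oscillating genus (A = 0.05 in proportion units, peak ZT19,
        baseline 0.2) among 20 flat genera has the smallest zero-amplitude p
        in >= 90% of 100 seeded runs."""
        from dataclasses import replace

        spec = replace(_flat_community(21),
                       baseline=tuple(np.r_[0.2, np.full(20, 0.8 / 20)]),
                       amplitude=tuple(np.r_[0.05, np.zeros(20)]),
                       acrophase_h=tuple(np.r_[19.0, np.zeros(20)]))
        hits = 0
        for seed in range(100):
            table = simulate_microbiome(spec, groups=("wt",), n_per_cell=5, seed=seed)
            res = taxa_rhythms(relative_abundance(table))
            best = res.rhythm.loc[res.rhythm["zero_amplitude_p"].idxmin(), "feature"]
            hits += best == "g00"
        assert hits >= 90

    def test_all_flat_null_calibration(self):
        """All-flat community: average fraction of taxa with unadjusted
        zero-amplitude p < 0.05 is 0.05 ± 0.02 over 100 runs."""
        spec = _flat_community(20)
        fracs = []
        for seed in range(100):
            table = simulate_microbiome(spec, groups=("wt",), n_per_cell=5, seed=seed)
            res = taxa_rhythms(relative_abundance(table))
            fracs.append((res.rhythm["zero_amplitude_p"] < 0.05).mean())
        assert abs(np.mean(fracs) - 0.05) <= 0.02

    def test_antiphase_genus_flagged_after_bh(self):
        """A genus oscillating 12 h apart between groups is flagged by the
        BH-adjusted acrophase comparison in >= 80% of runs."""
        from dataclasses import replace

        spec = replace(
            _flat_community(10, conc=1000.0),
            amplitude=tuple(np.r_[0.05, np.zeros(9)]),
            acrophase_h=tuple(np.r_[19.0, np.zeros(9)]),
            group_overrides={"ko": {"g00": (0.05, 7.0)}},
        )
        hits = 0
        for seed in range(50):
            table = simulate_microbiome(spec, groups=("wt", "ko"), n_per_cell=5, seed=seed)
            res = taxa_rhythms(relative_abundance(table))
            row = res.rhythm[(res.rhythm["feature"] == "g00")].iloc[0]
            hits += row["acrophase_comparison_p_adj"] < 0.01
        assert hits >= 0.80 * 50

    def test_library_size_invariance(self):
        """Rescaling library sizes leaves proportions, hence every p, fixed."""
        spec = _flat_community(6)
        table = simulate_microbiome(spec, groups=("wt",), n_per_cell=4, seed=3)
        scaled = TaxaTable(
            counts=table.counts * 10,
            taxonomy=table.taxonomy,
            metadata=table.metadata,
            mode="counts",
        )
        r1 = taxa_rhythms(relative_abundance(table)).rhythm
        r2 = taxa_rhythms(relative_abundance(scaled)).rhythm
        np.testing.assert_allclose(
            r1["zero_amplitude_p"].to_numpy(float),
            r2["zero_amplitude_p"].to_numpy(float),
            rtol=1e-12,
        )
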