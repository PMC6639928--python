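"""Community tables, PCoA embedding, crossed-DPCoA and diversity indices."""

import numpy as np
import pandas as pd
import pytest

from pondburst.community import (
    CommunityTable,
    CrossedDPCoA,
    crossed_dpcoa,
    diversity_by_period,
    gini_simpson,
    rao,
    richness,
    species_space,
    vote_and_tabulate,
    vote_majority,
)
from pondburst.events import BreedingEvent, EventWindow
from pondburst.exceptions import InvalidInputError


def make_table(P, species=None, event=None, period=None):
    species = species or [f"sp{i}" for i in range(P.shape[1])]
    idx = pd.MultiIndex.from_tuples(
        [("Ca", f"e{i}", f"t{i % 4 + 1}") for i in range(P.shape[0])],
        names=["site", "event", "period"],
    )
    prop = pd.DataFrame(P, index=idx, columns=species)
    return CommunityTable(
        proportions=prop,
        factor_event=pd.Series(event or [t[1] for t in idx], index=idx),
        factor_period=pd.Series(period or [t[2] for t in idx], index=idx),
    )


# ---------------------------------------------------------------------------
# species space (PCoA)
# ---------------------------------------------------------------------------


class TestSpeciesSpace:
    def test_equidistant_embedding_has_equal_pairwise_distances(self):
        coords = species_space("equidistant", species=list("abcde")).to_numpy()
        from scipy.spatial.distance import pdist

        d = pdist(coords)
        assert np.allclose(d, d[0], atol=1e-8)

    def test_two_species_sit_apart_by_their_dissimilarity(self):
        d = pd.DataFrame([[0, 0.4], [0.4, 0]], index=["a", "b"], columns=["a", "b"])
        coords = species_space(d).to_numpy()
        assert np.linalg.norm(coords[0] - coords[1]) == pytest.approx(0.4)

    def test_collinear_points_recovered_exactly(self):
        x = np.array([0.0, 1.0, 2.5, 4.0])
        d = pd.DataFrame(np.abs(x[:, None] - x[None, :]))
        coords = species_space(d).to_numpy()
        from scipy.spatial.distance import squareform, pdist

        assert np.allclose(squareform(pdist(coords)), d.to_numpy(), atol=1e-8)

    def test_agrees_with_scikit_bio_pcoa(self, rng):
        # independent oracle: embed a random Euclidean distance matrix
        pts = rng.random((6, 3))
        from scipy.spatial.distance import pdist, squareform

        d = pd.DataFrame(squareform(pdist(pts)))
        coords = species_space(d).to_numpy()
        from skbio.stats.ordination import pcoa

        ref = pcoa(d.to_numpy(), number_of_dimensions=3).samples.to_numpy()
        got = squareform(pdist(coords))
        want = squareform(pdist(ref))
        assert np.allclose(got, want, atol=1e-6)

    def test_non_euclidean_gets_lingoes_corrected(self):
        # a metric that is not Euclidean-embeddable without correction
        d = np.array(
            [
                [0, 1, 2, 1],
                [1, 0, 1, 2],
                [2, 1, 0, 1],
                [1, 2, 1, 0],
            ],
            dtype=float,
        )
        coords = species_space(pd.DataFrame(d)).to_numpy()
        assert np.isfinite(coords).all()

    def test_asymmetric_matrix_rejected(self):
        d = pd.DataFrame([[0, 1.0], [0.5, 0]])
        with pytest.raises(InvalidInputError):
            species_space(d)


# ---------------------------------------------------------------------------
# crossed DPCoA
# ---------------------------------------------------------------------------


def brute_force_dpcoa(P, Z, w=None):
    """Independent plain-DPCoA oracle: weighted PCA of community centroids."""
    n = P.shape[0]
    w = np.full(n, 1.0 / n) if w is None else w
    Y = P @ Z
    g = np.average(Y, axis=0, weights=w)
    Yc = Y - g
    C = (Yc * w[:, None]).T @ Yc
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    return vals[order], Yc @ vecs[:, order]


class TestCrossedDPCoA:
    def test_identical_communities_have_zero_inertia(self):
        P = np.tile([0.5, 0.3, 0.2], (4, 1))
        res = crossed_dpcoa(make_table(P), "equidistant", factor_a="event", factor_b="period")
        assert res.total_inertia == pytest.approx(0.0, abs=1e-12)

    def test_single_level_b_matches_bruteforce_plain_dpcoa(self, rng):
        # 4 communities x 3 species; each community its own A level
        P = rng.dirichlet(np.ones(3), size=4)
        table = make_table(P, period=["all"] * 4)  # factor B has one level
        sc = species_space("equidistant", species=table.species)
        res = crossed_dpcoa(table, sc, factor_a="event", factor_b="period")
        vals, proj = brute_force_dpcoa(P, sc.to_numpy())
        k = len(res.eigenvalues)
        assert np.allclose(res.eigenvalues, vals[:k], atol=1e-8)
        got = res.centered_community_coords.to_numpy()
        for j in range(k):  # up to axis sign
            assert np.allclose(got[:, j], proj[:, j], atol=1e-8) or np.allclose(
                got[:, j], -proj[:, j], atol=1e-8
            )

    def test_composition_depending_only_on_b_centres_to_zero(self):
        # rows within each B level identical -> B centring removes everything
        pa = [0.7, 0.2, 0.1]
        pb = [0.1, 0.3, 0.6]
        P = np.array([pa, pa, pb, pb])
        table = make_table(
            P, event=["a1", "a2", "a1", "a2"], period=["b1", "b1", "b2", "b2"]
        )
        res = crossed_dpcoa(table, "equidistant", factor_a="event", factor_b="period")
        assert res.total_inertia < 1e-10

    def test_inertia_equals_bruteforce_weighted_variance(self, rng):
        for _ in range(5):
            P = rng.dirichlet(np.ones(6), size=5)
            table = make_table(
                P,
                event=[f"a{i % 2}" for i in range(5)],
                period=[f"b{i % 2}" for i in range(5)],
            )
            sc = species_space("equidistant", species=table.species)
            model = CrossedDPCoA(table, sc, factor_a="event", factor_b="period")
            res = model.fit()
            # brute force: recompute centred A-level centroids and their
            # weighted squared norms
            Z = sc.to_numpy()
            Y = P @ Z
            w = np.full(5, 1 / 5)
            Yc = Y.copy()
            for lev in model.factor_b.unique():
                m = (model.factor_b == lev).to_numpy()
                Yc[m] -= np.average(Y[m], axis=0, weights=w[m])
            total = 0.0
            for lev in model.factor_a.unique():
                m = (model.factor_a == lev).to_numpy()
                c = np.average(Yc[m], axis=0, weights=w[m])
                total += w[m].sum() * np.dot(c, c)
            assert res.total_inertia == pytest.approx(total, abs=1e-8)

    def test_b_centring_is_exact(self, rng):
        P = rng.dirichlet(np.ones(4), size=8)
        table = make_table(
            P,
            event=[f"a{i % 4}" for i in range(8)],
            period=[f"b{i % 2}" for i in range(8)],
        )
        model = CrossedDPCoA(table, "equidistant", factor_a="event", factor_b="period")
        res = model.fit()
        cc = res.centered_community_coords
        for lev in model.factor_b.unique():
            m = (model.factor_b == lev).to_numpy()
            assert np.allclose(cc.to_numpy()[m].mean(axis=0), 0.0, atol=1e-10)

    def test_communities_lie_at_species_centroids(self, rng):
        P = rng.dirichlet(np.ones(5), size=6)
        table = make_table(P)
        sc = species_space("equidistant", species=table.species)
        res = crossed_dpcoa(table, sc)
        got = res.community_coords.to_numpy()
        want = P @ (sc.to_numpy() @ res.axes)
        assert np.allclose(got, want, atol=1e-10)

    def test_species_column_permutation_invariance(self, rng):
        P = rng.dirichlet(np.ones(4), size=6)
        t1 = make_table(P)
        perm = [2, 0, 3, 1]
        t2 = make_table(P[:, perm], species=[t1.species[i] for i in perm])
        r1 = crossed_dpcoa(t1, "equidistant")
        r2 = crossed_dpcoa(t2, "equidistant")
        assert np.allclose(r1.eigenvalues, r2.eigenvalues, atol=1e-10)
        a = r1.centered_community_coords.to_numpy()
        b = r2.centered_community_coords.to_numpy()
        for j in range(a.shape[1]):
            assert np.allclose(a[:, j], b[:, j], atol=1e-8) or np.allclose(
                a[:, j], -b[:, j], atol=1e-8
            )

    def test_missing_factor_a_level_rejected(self):
        P = np.array([[0.5, 0.5], [0.2, 0.8]])
        table = make_table(P)
        bad = pd.Series(["x", "x"], index=table.proportions.index)
        model = CrossedDPCoA(table, "equidistant", factor_a=bad, factor_b="event")
        model.factor_a = model.factor_a.map({"x": "x"})  # keep single level; fine
        res = model.fit()  # single level is allowed (zero inertia after centring?)
        assert np.isfinite(res.total_inertia)


# ---------------------------------------------------------------------------
# diversity indices
# ---------------------------------------------------------------------------


class TestIndices:
    def test_single_species_community(self):
        assert richness([1.0]) == 1
        assert gini_simpson([1.0]) == 0.0
        assert rao([1.0], np.zeros((1, 1))) == 0.0

    def test_two_species_rao_value(self):
        d = np.array([[0, 0.4], [0.4, 0]])
        assert rao([0.5, 0.5], d) == pytest.approx(0.2)

    def test_rao_equals_gini_simpson_for_unit_distances(self, rng):
        for _ in range(1000):
            p = rng.dirichlet(np.ones(rng.integers(2, 8)))
            d = 1.0 - np.eye(p.size)
            assert abs(rao(p, d) - gini_simpson(p)) < 1e-12

    def test_unnormalised_proportions_rejected(self):
        with pytest.raises(InvalidInputError):
            gini_simpson([0.5, 0.2])


# ---------------------------------------------------------------------------
# vote + tabulate and period diversity
# ---------------------------------------------------------------------------


def annotated_windows(small_config, n_events=2, error=0.0, seed=0):
    from pondburst.synthio import DEFAULT_TEMPLATES, generate_annotations, generate_weather, schedule_events

    weather = generate_weather(small_config, 0)
    events = schedule_events(weather, small_config, 0)[:n_events]
    windows = [EventWindow(ev, event_label=f"{ev.site_id}{k + 1}") for k, ev in enumerate(events)]
    recs = pd.DatetimeIndex(sorted(set().union(*(w.subsample("2h") for w in windows))))
    _, tables = generate_annotations(events, DEFAULT_TEMPLATES, recs, error, 3, seed=seed)
    site = events[0].site_id
    keyed = []
    for t in tables:
        idx = pd.MultiIndex.from_product([[site], t.index], names=["site", "timestamp"])
        keyed.append(t.set_axis(idx))
    return keyed, windows


class TestVoteAndTabulate:
    def test_majority_vote_of_identical_tables(self):
        t = pd.DataFrame([[1, 0], [0, 1]], columns=["a", "b"])
        pd.testing.assert_frame_equal(vote_majority([t, t, t]), t)

    def test_ten_windows_subsample_to_240_recordings(self):
        onsets = pd.date_range("2015-12-01", periods=10, freq="5D")
        windows = [
            EventWindow(BreedingEvent("Ca", t, t + pd.Timedelta(hours=30)))
            for t in onsets
        ]
        total = sum(len(w.subsample("2h")) for w in windows)
        assert total == 240

    def test_rows_at_most_events_times_periods(self, small_config):
        tables, windows = annotated_windows(small_config)
        table = vote_and_tabulate(tables, windows)
        assert len(table) <= len(windows) * 4
        assert np.allclose(table.proportions.sum(axis=1), 1.0)

    def test_period_composition_reflects_pools(self, small_config):
        from pondburst.synthio import DEFAULT_TEMPLATES

        tables, windows = annotated_windows(small_config, error=0.0)
        table = vote_and_tabulate(tables, windows)
        pre = {t.species_id for t in DEFAULT_TEMPLATES if t.pool == "pre_explosive"}
        expl = {t.species_id for t in DEFAULT_TEMPLATES if t.pool == "explosive"}
        for (site, event, period), row in table.proportions.iterrows():
            present = set(row[row > 0].index)
            if period in ("t1", "t2"):
                assert pre <= present and not (expl & present)
            elif period == "t4":
                assert expl <= present and not (pre & present)

    def test_t3_richness_at_least_neighbours(self, small_config):
        tables, windows = annotated_windows(small_config, error=0.0)
        table = vote_and_tabulate(tables, windows)
        per_row, _ = diversity_by_period(table)
        r = per_row.reset_index().pivot_table(
            index="event", columns="period", values="richness"
        )  # index levels (site, event, period) become columns
        assert (r["t3"] >= r[["t2", "t4"]].max(axis=1)).all()


class TestDiversityByPeriod:
    def test_clustered_explosive_pool_drops_rao_at_t4(self, small_config):
        from pondburst.spectra import dcf_matrix, mean_spectrum
        from pondburst.synthio import DEFAULT_TEMPLATES, synthesize_clip

        # focal-call convention: low noise floor (clips must pass the
        # 30 dB SNR screen before entering the dissimilarity matrix)
        specs = {
            t.species_id: mean_spectrum(
                synthesize_clip(DEFAULT_TEMPLATES, {t.species_id}, 2.0, 44100, 0.0001, 5),
                44100,
            )
            for t in DEFAULT_TEMPLATES
        }
        d = dcf_matrix(specs)
        tables, windows = annotated_windows(small_config, error=0.05, seed=3)
        table = vote_and_tabulate(tables, windows)
        per_row, by_period = diversity_by_period(table, d)
        assert by_period.loc["t4", ("rao", "mean")] < by_period.loc["t1", ("rao", "mean")]

    def test_null_control_runs_with_equidistant_species(self, small_config):
        tables, windows = annotated_windows(small_config, error=0.05, seed=4)
        table = vote_and_tabulate(tables, windows)
        per_row, by_period = diversity_by_period(table, d=None)
        # with unit distances Rao collapses to Gini-Simpson; no ordering is
        # implied between periods
        assert np.allclose(per_row["rao"], per_row["gini_simpson"], atol=1e-12)
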