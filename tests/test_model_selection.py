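"""Bayesian model selection: enumeration, marginal likelihoods, selection rules."""

import numpy as np
import pytest

from medtriad import (
    CausalStructure,
    CorrelationTriple,
    MeasurementErrorConfig,
    MediationModel,
    Priors,
    TripletDataset,
    ValidationError,
    enumerate_models,
    log_marginal_likelihood,
    sample_configs,
    select_from_correlations,
    select_model,
    simulate_dataset,
    weakest_correlation_rule,
)
from medtriad.correlation_model import Role
from medtriad.model_selection import DesignError, log_ml_from_correlations
from medtriad.simulator import SimulationDesign

C = CausalStructure


def _mk(*edges):
    return MediationModel(frozenset(edges))


class TestEnumeration:
    def test_three_choice_set(self):
        labels = [m.label for m in enumerate_models("three_choice")]
        assert labels == ["Causal", "Independent", "Reactive"]

    def test_expanded_set_size_and_labels(self):
        models = enumerate_models("expanded")
        assert len(models) == 10
        labels = [m.label for m in models]
        for named in ("Causal", "Independent", "Reactive", "Complex"):
            assert labels.count(named) == 1
        assert labels.count("other-nonmediation") == 6

    def test_excluded_duplicates_absent(self):
        edge_sets = {m.edges for m in enumerate_models("expanded")}
        assert frozenset({"b_rev"}) not in edge_sets
        assert frozenset({"a", "c", "b_rev"}) not in edge_sets

    def test_acyclicity(self):
        with pytest.raises(ValidationError, match="acyclicity"):
            _mk("b", "b_rev")

    def test_parent_maps(self):
        m = _mk("a", "b_rev")
        assert m.parents_m == ("x", "y") and m.parents_y == ()
        m = _mk("b", "c")
        assert m.parents_m == () and m.parents_y == ("x", "m")


@pytest.fixture(scope="module")
def datasets():
    """A batch of random triplet datasets across structures."""
    out = []
    for i, s in enumerate([C.CAUSAL, C.INDEPENDENT, C.REACTIVE]):
        for j, config in enumerate(
            sample_configs(SimulationDesign(s, n_configs=34, seed=60 + i))
        ):
            out.append(simulate_dataset(config, 120, seed=1000 + 100 * i + j))
    return out


class TestMarginalLikelihood:
    def test_correlation_path_matches_design_path(self, datasets):
        """The sufficient-statistic scorer equals the design-matrix scorer."""
        models = enumerate_models("expanded")
        for ds in datasets[:20]:
            rxy = np.corrcoef(ds.x, ds.y)[0, 1]
            rxm = np.corrcoef(ds.x, ds.m)[0, 1]
            rym = np.corrcoef(ds.y, ds.m)[0, 1]
            fast = log_ml_from_correlations(rxy, rxm, rym, ds.n, "expanded")
            slow = np.array([log_marginal_likelihood(ds, m) for m in models])
            assert np.max(np.abs(fast - slow)) < 1e-8

    def test_reversed_single_edge_is_likelihood_equivalent(self, datasets):
        """The excluded Y->M model scores identically to its M->Y counterpart."""
        for ds in datasets:
            lb = log_marginal_likelihood(ds, _mk("b"))
            lbr = log_marginal_likelihood(ds, _mk("b_rev"))
            assert abs(lb - lbr) < 1e-8

    def test_excluded_complete_model_nearly_equivalent(self, datasets):
        """Both complete DAGs are Markov equivalent; under the factored
        per-node prior their marginal likelihoods agree only approximately
        (they coincide in the flat-prior limit of the fit term)."""
        diffs = np.abs(
            [
                log_marginal_likelihood(ds, _mk("a", "b", "c"))
                - log_marginal_likelihood(ds, _mk("a", "c", "b_rev"))
                for ds in datasets
            ]
        )
        assert np.max(diffs) < 2.0  # bounded on the log scale
        assert np.median(diffs) < 0.1  # and typically tiny
        assert np.max(diffs) > 0  # but not an exact identity

    def test_null_data_prefers_no_edges(self):
        rng = np.random.default_rng(0)
        n, reps = 200, 1000
        x = rng.standard_normal((reps, n))
        m = rng.standard_normal((reps, n))
        y = rng.standard_normal((reps, n))

        def rowcorr(a, b):
            a = a - a.mean(1, keepdims=True)
            b = b - b.mean(1, keepdims=True)
            return (a * b).sum(1) / np.sqrt((a**2).sum(1) * (b**2).sum(1))

        lml = log_ml_from_correlations(
            rowcorr(x, y), rowcorr(x, m), rowcorr(y, m), n, "expanded"
        )
        models = enumerate_models("expanded")
        i_null = [m_.edges for m_ in models].index(frozenset())
        i_causal = [m_.label for m_ in models].index("Causal")
        wins = np.mean(lml[:, i_null] > lml[:, i_causal])
        assert wins >= 0.95
        # prior-complexity penalty: the extra edge lowers the evidence on average
        i_a = [m_.edges for m_ in models].index(frozenset({"a"}))
        assert np.mean(lml[:, i_a] - lml[:, i_null]) < 0

    def test_scale_invariance(self, datasets):
        for ds in datasets[:10]:
            scaled = TripletDataset(x=ds.x, m=10 * ds.m, y=10 * ds.y)
            a = select_model(ds, "expanded").selected
            b = select_model(scaled, "expanded").selected
            assert a == b

    def test_rank_deficient_design_raises(self):
        n = 60
        rng = np.random.default_rng(1)
        ds = TripletDataset(
            x=np.ones(n), m=rng.standard_normal(n), y=rng.standard_normal(n)
        )
        with pytest.raises(DesignError):
            log_marginal_likelihood(ds, _mk("a", "c"))

    def test_multistate_block_enters_as_predictors(self, causal_config):
        ds = simulate_dataset(causal_config, 300, seed=5, x_kind="multistate")
        post = select_model(ds, "three_choice")
        assert post.classification in ("Causal", "Independent", "Reactive")

    def test_covariates_held_fixed_across_models(self, causal_config):
        rng = np.random.default_rng(2)
        ds = simulate_dataset(causal_config, 400, seed=9)
        cov = rng.standard_normal(400)
        shifted = TripletDataset(
            x=ds.x, m=ds.m + 2 * cov, y=ds.y + 2 * cov, covariates=cov[:, None]
        )
        plain = select_model(ds, "three_choice").classification
        adjusted = select_model(shifted, "three_choice").classification
        assert adjusted == plain


class TestSelectModel:
    def test_posteriors_normalized(self, datasets):
        for ds in datasets[:10]:
            post = select_model(ds, "expanded")
            assert post.posterior.sum() == pytest.approx(1.0, abs=1e-12)
            assert post.posterior.argmax() == post.log_ml.argmax()

    def test_strong_errorfree_causal_selected(self, errorfree_config):
        ds = simulate_dataset(errorfree_config, 5000, seed=4)
        post = select_model(ds, "three_choice")
        assert post.classification == "Causal"
        assert post.posterior.max() > 0.95

    def test_mediator_error_drives_complex(self):
        """Measurement error in M pushes expanded selection to partial mediation."""
        causal = CorrelationTriple(0.72, 0.9, 0.8, role=Role.CAUSAL)
        config = MeasurementErrorConfig(C.CAUSAL, causal, 1.0, 0.8, 1.0)
        wins = 0
        reps = 60
        for i in range(reps):
            ds = simulate_dataset(config, 5000, seed=3000 + i)
            wins += select_model(ds, "expanded").classification == "Complex"
        assert wins > reps / 2

    def test_symmetric_correlations_give_uniform_posterior(self):
        lml = log_ml_from_correlations(0.5, 0.5, 0.5, 200, "three_choice")
        post = np.exp(lml - lml.max())
        post /= post.sum()
        assert np.allclose(post, 1 / 3, atol=1e-12)

    def test_as_row_contains_all_models(self, datasets):
        row = select_model(datasets[0], "expanded").as_row()
        assert sum(k.startswith("lnML[") for k in row) == 10
        assert row["classification"] in (
            "Causal", "Independent", "Reactive", "Complex", "other-nonmediation"
        )


class TestWeakestCorrelationRule:
    @pytest.mark.parametrize(
        "triple, expected",
        [
            ((0.5, 0.8, 0.7), "Causal"),
            ((0.8, 0.7, 0.5), "Independent"),
            ((0.7, 0.5, 0.8), "Reactive"),
            ((0.5, 0.5, 0.8), "ambiguous"),
        ],
    )
    def test_examples(self, triple, expected):
        t = CorrelationTriple(*triple, role=Role.ESTIMATED)
        assert weakest_correlation_rule(t) == expected

    def test_multistate_not_applicable(self, causal_config):
        ds = simulate_dataset(causal_config, 100, seed=0, x_kind="multistate")
        with pytest.raises(ValidationError, match="not applicable"):
            weakest_correlation_rule(ds)

    def test_agrees_with_bayesian_three_choice(self):
        """Rule vs Bayesian selection on >= 2,000 simulated datasets."""
        rng = np.random.default_rng(44)
        agree = total = 0
        for i, s in enumerate([C.CAUSAL, C.INDEPENDENT, C.REACTIVE]):
            configs = sample_configs(SimulationDesign(s, n_configs=700, seed=70 + i))
            for config in configs:
                ds = simulate_dataset(config, 200, rng)
                rule = weakest_correlation_rule(ds)
                if rule == "ambiguous":
                    continue
                rxy = np.corrcoef(ds.x, ds.y)[0, 1]
                rxm = np.corrcoef(ds.x, ds.m)[0, 1]
                rym = np.corrcoef(ds.y, ds.m)[0, 1]
                bayes = str(select_from_correlations(rxy, rxm, rym, 200, "three_choice"))
                total += 1
                agree += bayes == rule
        assert total >= 2000
        assert agree / total >= 0.99
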