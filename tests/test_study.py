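"""Study driver: grids, seeds, accuracy tables, resampling design."""

import numpy as np
import pandas as pd
import pytest

from respstyles import (
    FitOptions,
    GenCondition,
    ResponseMatrix,
    StudyConfig,
    classification_accuracy,
    default_conditions,
    factor_marginals,
    generate_dataset,
    resample_study,
    run_replication,
    run_study,
)
from respstyles.study import _fix_unendorsed, derive_seed, slash_table

FAST = FitOptions(tol_loglik=5e-2, tol_param=5e-2, max_cycles=20)


def _toy_records():
    """Constructed records: accuracy 100% iff N=1000, one cell 3/4 correct."""
    rows = []
    for n, correct, total in ((250, 3, 4), (1000, 4, 4)):
        for i in range(total):
            rows.append({"kind": "null", "n_persons": n, "n_items": 10,
                         "n_substantive": 1, "sigma_rs": None, "r_rs": None,
                         "slope_corr": None,
                         "selected_bic": "null" if (n == 1000 or i < correct)
                         else "ers_mrs",
                         "selected_aic": "null" if n == 1000 else "ers_mrs",
                         "selected_combined": "null"})
    return pd.DataFrame(rows)


class TestGrids:
    def test_default_cell_counts(self):
        assert len(default_conditions("null")) == 12
        assert len(default_conditions("ers_mrs")) == 36
        assert len(default_conditions("ers_plus_mrs")) == 216
        assert len(StudyConfig().conditions()) == 264

    def test_unknown_regime_rejected(self):
        with pytest.raises(ValueError):
            default_conditions("mixture")


class TestSeeds:
    def test_seed_depends_on_condition_content_not_grid(self):
        a = GenCondition("null", 250, 10, 1)
        b = GenCondition("null", 250, 20, 1)
        assert derive_seed(1, a, 0) != derive_seed(1, b, 0)
        assert derive_seed(1, a, 0) == derive_seed(1, a, 0)
        assert derive_seed(1, a, 0) != derive_seed(1, a, 1)
        assert derive_seed(2, a, 0) != derive_seed(1, a, 0)

    def test_seeds_fit_in_31_bits(self):
        cond = GenCondition("ers_mrs", 500, 20, 2, sigma_rs=1.5)
        for rep in range(50):
            assert 0 <= derive_seed(123, cond, rep) < 2 ** 31


class TestRunReplication:
    def test_record_contract_and_determinism(self):
        condition = GenCondition("null", 120, 4, 1)
        a = run_replication(condition, 0, base_seed=7, options=FAST)
        b = run_replication(condition, 0, base_seed=7, options=FAST)
        a.pop("runtime_s"), b.pop("runtime_s")
        assert a == b
        for criterion in ("aic", "bic", "combined"):
            assert a[f"selected_{criterion}"] in ("null", "ers_mrs",
                                                  "ers_plus_mrs")
        assert a["error"] == ""

    def test_failures_recorded_not_raised(self):
        # a 2-person sample cannot cover every category: generation aborts,
        # and the record carries the error
        condition = GenCondition("null", 2, 4, 1)
        record = run_replication(condition, 0, options=FAST)
        assert record["selected_aic"] is None
        assert "RuntimeError" in record["error"]


class TestAccuracyTables:
    def test_cell_arithmetic(self):
        acc = classification_accuracy(_toy_records(), ("n_persons",), "bic")
        assert acc.loc[acc.n_persons == 250, "accuracy"].iloc[0] == 75.0
        assert acc.loc[acc.n_persons == 1000, "accuracy"].iloc[0] == 100.0

    def test_overall_aggregate(self):
        acc = classification_accuracy(_toy_records(), (), "bic")
        assert acc["accuracy"].iloc[0] == pytest.approx(7 / 8 * 100)
        assert int(acc["n"].iloc[0]) == 8

    def test_accuracy_bounded(self):
        acc = classification_accuracy(_toy_records(), ("n_persons",), "aic")
        assert acc["accuracy"].between(0, 100).all()

    def test_unknown_factor_rejected(self):
        with pytest.raises(ValueError, match="unknown factor"):
            classification_accuracy(_toy_records(), ("sample_size",), "bic")

    def test_marginals_match_binary_design(self):
        marg = factor_marginals(_toy_records(), "aic")
        n_rows = marg[marg.factor == "n_persons"].set_index("level")
        assert n_rows.loc[1000, "accuracy"] == 100.0
        assert n_rows.loc[250, "accuracy"] == 0.0
        # null records carry no response-style factors
        assert set(marg.factor) == {"n_persons", "n_items", "n_substantive"}

    def test_marginals_are_weighted_cell_means(self):
        marg = factor_marginals(_toy_records(), "bic")
        row = marg[(marg.factor == "n_items") & (marg.level == 10)]
        assert row["accuracy"].iloc[0] == pytest.approx(7 / 8 * 100)
        assert int(row["n"].iloc[0]) == 8

    def test_slash_table_formats_slope_correlation_pair(self):
        rows = []
        for sc, correct in ((0, 4), (1, 2)):
            for i in range(4):
                rows.append({"kind": "ers_plus_mrs", "n_persons": 500,
                             "n_items": 10, "n_substantive": 1,
                             "sigma_rs": 1.0, "r_rs": 0.0, "slope_corr": sc,
                             "selected_bic": "ers_plus_mrs" if i < correct
                             else "null"})
        table = slash_table(pd.DataFrame(rows), "bic")
        assert table["accuracy_corr1/corr0"].iloc[0] == "50/100"


class TestRunStudy:
    def test_reduced_run_bookkeeping(self):
        config = StudyConfig(regimes=("null",), n_levels=(120,),
                             j_levels=(4,), d_levels=(1,), replications=2,
                             base_seed=5, fit_options=FAST)
        records = run_study(config)
        assert len(records) == 2
        acc = classification_accuracy(records, ("n_persons",), "bic")
        assert len(acc) == 1 and int(acc["n"].iloc[0]) == 2

    def test_replication_prefix_is_stable(self):
        """Doubling replications reuses the same seed stream prefix."""
        base = dict(regimes=("null",), n_levels=(120,), j_levels=(4,),
                    d_levels=(1,), base_seed=5, fit_options=FAST)
        two = run_study(StudyConfig(replications=2, **base))
        three = run_study(StudyConfig(replications=3, **base))
        pd.testing.assert_frame_equal(
            two.drop(columns="runtime_s"),
            three.iloc[:2].reset_index(drop=True).drop(columns="runtime_s"))


class TestResampleStudy:
    @pytest.fixture(scope="class")
    def big_data(self):
        condition = GenCondition("ers_mrs", 400, 6, 1, sigma_rs=1.5, seed=13)
        return generate_dataset(condition)[0]

    def test_degenerate_resample_reproduces_full_data_selection(self, big_data):
        from respstyles import fitted_model_battery
        from respstyles.selection import criterion_table
        full = criterion_table(fitted_model_battery(big_data, options=FAST))
        full_choice = full.loc[full.selected_bic, "model"].iloc[0]
        records = resample_study(big_data, big_data.n_persons,
                                 big_data.n_items, n_resamples=1,
                                 seed=3, options=FAST)
        assert records["selected_bic"].iloc[0] == full_choice

    def test_sampling_without_replacement(self, big_data):
        records = resample_study(big_data, 50, 4, n_resamples=3, seed=1,
                                 options=FAST)
        assert len(records) == 3
        assert (records["n_persons"] == 50).all()

    def test_oversized_subsample_rejected(self, big_data):
        with pytest.raises(ValueError, match="exceed"):
            resample_study(big_data, big_data.n_persons + 1, 4)

    def test_unendorsed_fix_fills_first_missing(self):
        responses = np.array([[0, 1], [1, 2], [-1, 3], [-1, 0]])
        fixed, unfixable = _fix_unendorsed(responses, 5)
        # categories 2, 3, 4 unendorsed for item 0 -> first two missing cells
        # are filled in category order; category 4 has no slot left
        assert fixed[2, 0] == 2 and fixed[3, 0] == 3
        assert (0, 4) in unfixable
        # item 1 misses category 4 but has no missing entry at all
        assert (1, 4) in unfixable
        assert np.array_equal(fixed[:, 1], responses[:, 1])

    def test_scale_structure_keeps_both_scales(self):
        condition = GenCondition("null", 300, 6, 2, seed=17)
        data, *_ = generate_dataset(condition)
        records = resample_study(data, 100, 2, n_resamples=4,
                                 item_scales=[0, 0, 0, 1, 1, 1], seed=2,
                                 options=FAST)
        assert (records["error"] == "").all()
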