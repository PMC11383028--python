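"""Preprocessing: filter rule, normalizations, three-branch imputation.

The filter and imputation-branch logic are checked against independent
brute-force rule evaluators on randomized fixtures, in addition to the
worked examples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from proxidiff.containers import PeptideQuantMatrix, PipelineConfig
from proxidiff.errors import (
    ConsistencyError,
    DegenerateInputError,
    ReproducibilityError,
    StateError,
)
from proxidiff.preprocess import (
    BRANCH_BINNED,
    BRANCH_LOW,
    BRANCH_MISALIGNED,
    BRANCH_NONE,
    filter_peptides,
    impute,
    total_intensity_normalize,
    trimmed_mean_normalize,
)
from proxidiff.simulate import SynthParams, make_design, simulate_dataset

from conftest import build_matrix


# ---------------------------------------------------------------- oracles


def filter_oracle(observed_row: np.ndarray, group_cols: dict[str, list[int]]) -> bool:
    """Naive re-statement of the keep rule for one peptide."""
    if observed_row.sum() < 2:
        return False
    for cols in group_cols.values():
        sub = observed_row[cols]
        if sub.mean() >= 0.5:
            return True
    return False


def branch_oracle(values, observed, cutoff, is_spqc):
    """Naive branch selection for one (peptide, group)."""
    n_missing = int((~observed).sum())
    if n_missing == 0:
        return BRANCH_NONE
    if is_spqc:
        return BRANCH_LOW
    if n_missing / len(observed) < 0.5:
        return BRANCH_BINNED
    obs_vals = values[observed]
    if obs_vals.size and obs_vals.mean() > cutoff:
        return BRANCH_MISALIGNED
    return BRANCH_LOW


# ----------------------------------------------------------------- filter


class TestFilterPeptides:
    def make(self, obs_patterns, design):
        values = {
            f"P{i}": [1e6 if o else None for o in row]
            for i, row in enumerate(obs_patterns)
        }
        return build_matrix(values, design.sample_ids)

    def test_single_observation_removed(self, design12):
        row = [False] * 15
        row[0] = True
        m = self.make([row], design12)
        assert filter_peptides(m, design12).shape[0] == 0

    def test_spread_across_groups_below_half_removed(self, design12):
        # observed once in each of two groups: passes the >=2 rule but no
        # group reaches 50% of replicates
        row = [False] * 15
        row[0] = True  # WT_CYT_1
        row[6] = True  # GS_CYT_1
        m = self.make([row], design12)
        assert filter_peptides(m, design12).shape[0] == 0

    def test_two_of_three_in_one_group_kept(self, design12):
        row = [False] * 15
        row[3] = row[4] = True  # WT_EZR_1, WT_EZR_2
        m = self.make([row], design12)
        assert filter_peptides(m, design12).shape[0] == 1

    def test_matches_bruteforce_oracle_on_random_patterns(self, design12, rng):
        cols = list(design12.sample_ids)
        group_cols = {
            g: [cols.index(s) for s in samples]
            for g, samples in design12.biological_groups().items()
        }
        patterns = rng.random((300, 15)) < rng.uniform(0.05, 0.9, (300, 1))
        m = self.make(patterns, design12)
        kept = set(filter_peptides(m, design12).peptide_ids)
        expected = {
            f"P{i}" for i, row in enumerate(patterns) if filter_oracle(row, group_cols)
        }
        assert kept == expected

    def test_idempotent_and_order_preserving(self, design12, rng):
        patterns = rng.random((60, 15)) < 0.5
        m = self.make(patterns, design12)
        once = filter_peptides(m, design12)
        twice = filter_peptides(once, design12)
        assert list(once.peptide_ids) == list(twice.peptide_ids)
        assert [p for p in m.peptide_ids if p in set(once.peptide_ids)] == list(
            once.peptide_ids
        )

    def test_design_mismatch_rejected(self, design12):
        m = build_matrix({"P0": [1.0]}, ["unknown_sample"])
        with pytest.raises(ConsistencyError):
            filter_peptides(m, design12)


# -------------------------------------------------------- total normalize


class TestTotalIntensityNormalize:
    def test_two_sample_arithmetic(self):
        m = build_matrix(
            {"a": [40.0, 150.0], "b": [60.0, 50.0]}, ["s1", "s2"], stage="filtered"
        )
        out, factors = total_intensity_normalize(m)
        assert factors["s1"] == pytest.approx(1.5)
        assert factors["s2"] == pytest.approx(0.75)
        sums = out.intensity.sum(axis=0)
        assert sums["s1"] == pytest.approx(150.0)
        assert sums["s2"] == pytest.approx(150.0)

    def test_equal_sums_identity(self):
        m = build_matrix({"a": [10.0, 10.0], "b": [5.0, 5.0]}, ["s1", "s2"],
                         stage="filtered")
        out, factors = total_intensity_normalize(m)
        assert np.allclose(factors, 1.0)
        pd.testing.assert_frame_equal(out.intensity, m.intensity)

    def test_single_sample_unchanged(self):
        m = build_matrix({"a": [10.0], "b": [5.0]}, ["s1"], stage="filtered")
        out, factors = total_intensity_normalize(m)
        assert factors["s1"] == 1.0

    def test_column_sums_equal_and_idempotent(self, rng):
        vals = {f"P{i}": list(rng.lognormal(10, 1, 4)) for i in range(50)}
        m = build_matrix(vals, ["a", "b", "c", "d"], stage="filtered")
        out, _ = total_intensity_normalize(m)
        sums = out.intensity.sum(axis=0).to_numpy()
        assert np.allclose(sums, sums[0], rtol=1e-9)
        again, factors2 = total_intensity_normalize(
            PeptideQuantMatrix(out.intensity, out.observed, "filtered")
        )
        assert np.allclose(factors2, 1.0, rtol=1e-12)

    def test_zero_total_sample_rejected(self):
        m = build_matrix({"a": [1.0, None]}, ["s1", "s2"], stage="filtered")
        with pytest.raises(DegenerateInputError):
            total_intensity_normalize(m)


# ------------------------------------------------------------- imputation


def tn(values, sample_ids):
    return build_matrix(values, sample_ids, stage="total_normalized")


class TestImpute:
    def pad(self, group_rows, design):
        """Place per-group rows into the full 15-column design plus
        high-abundance filler peptides giving the bins context."""
        cols = list(design.sample_ids)
        values = {}
        rng = np.random.default_rng(0)
        for i in range(40):  # context peptides spanning the intensity range
            values[f"ctx{i}"] = list(rng.lognormal(np.log(1e6), 2.0, len(cols)))
        values.update(group_rows)
        return tn(values, cols)

    def test_branch_binned_normal_keeps_observed(self, design12, config):
        row = [1e6] * 15
        row[3], row[4], row[5] = 1e6, None, 1.2e6  # WT_EZR: 1 of 3 missing
        m = self.pad({"pep": row}, design12)
        out, audit = impute(m, design12, config)
        assert audit.branch_for("pep", "WT_EZR") == BRANCH_BINNED
        assert out.intensity.loc["pep", "WT_EZR_1"] == 1e6
        assert out.intensity.loc["pep", "WT_EZR_3"] == 1.2e6
        assert out.intensity.loc["pep", "WT_EZR_2"] > 0
        assert out.observed.to_numpy().all()

    def test_branch_misaligned_zeroes_whole_group(self, design12, config):
        row = [1e6] * 15
        row[3], row[4], row[5] = 6e6, None, None  # mean 6e6 > 5e6, 2/3 missing
        m = self.pad({"pep": row}, design12)
        out, audit = impute(m, design12, config)
        assert audit.branch_for("pep", "WT_EZR") == BRANCH_MISALIGNED
        assert (out.intensity.loc["pep", ["WT_EZR_1", "WT_EZR_2", "WT_EZR_3"]] == 0).all()
        # other groups untouched
        assert out.intensity.loc["pep", "WT_CYT_1"] == 1e6

    def test_branch_low_value_uses_global_quantile(self, design12, config):
        row = [1e6] * 15
        row[3], row[4], row[5] = 1e4, None, None  # mean 1e4 < cutoff
        m = self.pad({"pep": row}, design12)
        out, audit = impute(m, design12, config)
        assert audit.branch_for("pep", "WT_EZR") == BRANCH_LOW
        obs_vals = m.intensity.to_numpy()[m.observed.to_numpy()]
        q = np.quantile(obs_vals, config.low_percentile)
        assert out.intensity.loc["pep", "WT_EZR_2"] == pytest.approx(q)
        assert out.intensity.loc["pep", "WT_EZR_3"] == pytest.approx(q)
        assert audit.low_value_floor == pytest.approx(q)

    def test_spqc_group_only_receives_low_value(self, design12, config):
        row = [1e7] * 15
        row[12], row[13] = None, None  # SPQC mostly missing, high mean
        m = self.pad({"pep": row}, design12)
        out, audit = impute(m, design12, config)
        assert audit.branch_for("pep", "SPQC") == BRANCH_LOW

    def test_seeded_determinism(self, design12, config):
        p = SynthParams(seed=11, n_proteins=80)
        matrix, _, design, _ = simulate_dataset(p)
        from proxidiff.preprocess import filter_peptides as fp
        m, _ = total_intensity_normalize(fp(matrix, design))
        a, _ = impute(m, design, config)
        b, _ = impute(m, design, config)
        pd.testing.assert_frame_equal(a.intensity, b.intensity)

    def test_no_missing_is_identity(self, design12, config):
        row = list(np.linspace(1e5, 1e6, 15))
        m = self.pad({"pep": row}, design12)
        out, audit = impute(m, design12, config)
        pd.testing.assert_frame_equal(out.intensity, m.intensity)
        assert audit.records.empty

    def test_unseeded_config_rejected(self, design12):
        m = self.pad({}, design12)
        with pytest.raises(ReproducibilityError):
            impute(m, design12, PipelineConfig())

    def test_branch_selection_matches_oracle_on_random_fixtures(self, design12):
        config = PipelineConfig(seed=123)
        rng = np.random.default_rng(99)
        cols = list(design12.sample_ids)
        groups = design12.imputation_groups()
        for trial in range(30):
            values = {}
            for i in range(50):
                row = rng.lognormal(np.log(1e6), 2.5, 15)
                mask = rng.random(15) < rng.uniform(0, 0.9)
                values[f"P{i}"] = [None if mk else v for v, mk in zip(row, mask)]
            m = tn(values, cols)
            if not m.observed.to_numpy().any():
                continue
            _, audit = impute(m, design12, config)
            for pid in m.peptide_ids:
                for gname, gsamples in groups.items():
                    vals = m.intensity.loc[pid, gsamples].to_numpy()
                    obs = m.observed.loc[pid, gsamples].to_numpy()
                    expect = branch_oracle(vals, obs, config.misaligned_cutoff,
                                           gname == "SPQC")
                    assert audit.branch_for(pid, gname) == expect, (trial, pid, gname)

    def test_observed_preserved_outside_branch2(self, design12, config):
        p = SynthParams(seed=13, n_proteins=120)
        matrix, _, design, _ = simulate_dataset(p)
        from proxidiff.preprocess import filter_peptides as fp
        m, _ = total_intensity_normalize(fp(matrix, design))
        out, audit = impute(m, design, config)
        zeroed = set(
            audit.records.loc[audit.records["branch"] == BRANCH_MISALIGNED,
                              "peptide_id"]
        )
        obs = m.observed.to_numpy()
        before = m.intensity.to_numpy()
        after = out.intensity.to_numpy()
        keep = np.array([pid not in zeroed for pid in m.peptide_ids])
        assert np.array_equal(before[keep][obs[keep]], after[keep][obs[keep]])


# ----------------------------------------------------------- trimmed mean


class TestTrimmedMeanNormalize:
    def imputed(self, values, sample_ids):
        return build_matrix(values, sample_ids, stage="imputed")

    def test_hand_arithmetic_one_to_ten(self, config):
        vals = {f"P{i}": [float(i + 1), float(i + 1)] for i in range(10)}
        m = self.imputed(vals, ["s1", "s2"])
        out, factors = trimmed_mean_normalize(m, config)
        # trimmed mean of 1..10 at 10% per tail = mean(2..9) = 5.5; both
        # samples identical so nothing changes
        assert np.allclose(factors, 1.0)
        assert out.intensity.loc["P0", "s1"] == 1.0

    def test_identity_when_trimmed_means_match(self, config, rng):
        col = np.sort(rng.lognormal(10, 1, 30))
        vals = {f"P{i}": [col[i], col[29 - i]] for i in range(30)}
        m = self.imputed(vals, ["s1", "s2"])
        out, factors = trimmed_mean_normalize(m, config)
        assert np.allclose(factors, 1.0, rtol=1e-12)

    def test_doubling_a_sample_halves_its_factor(self, config, rng):
        base = rng.lognormal(10, 1, 40)
        m1 = self.imputed({f"P{i}": [base[i], base[i]] for i in range(40)},
                          ["s1", "s2"])
        m2 = self.imputed({f"P{i}": [base[i], 2 * base[i]] for i in range(40)},
                          ["s1", "s2"])
        _, f1 = trimmed_mean_normalize(m1, config)
        _, f2 = trimmed_mean_normalize(m2, config)
        rel1 = f1["s2"] / f1["s1"]
        rel2 = f2["s2"] / f2["s1"]
        assert rel2 / rel1 == pytest.approx(0.5, rel=1e-9)

    def test_post_trimmed_means_equal_and_zeros_preserved(self, config, rng):
        vals = {f"P{i}": list(rng.lognormal(10, 2, 3)) for i in range(60)}
        vals["Pz"] = [0.0, 0.0, 0.0]
        m = self.imputed(vals, ["a", "b", "c"])
        out, factors = trimmed_mean_normalize(m, config)
        assert (factors > 0).all()
        assert (out.intensity.loc["Pz"] == 0).all()
        tms = []
        for c in ("a", "b", "c"):
            pos = np.sort(out.intensity[c][out.intensity[c] > 0].to_numpy())
            cut = int(np.floor(config.trim_fraction * pos.size))
            tms.append(pos[cut: pos.size - cut].mean())
        assert np.allclose(tms, tms[0], rtol=1e-9)

    def test_too_few_positive_values_rejected(self, config):
        m = self.imputed({"a": [1.0, 1.0], "b": [0.0, 2.0]}, ["s1", "s2"])
        with pytest.raises(DegenerateInputError):
            trimmed_mean_normalize(m, config)

    def test_wrong_stage_rejected(self, config):
        m = build_matrix({"a": [1.0]}, ["s1"], stage="raw")
        with pytest.raises(StateError):
            trimmed_mean_normalize(m, config)
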