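import numpy as np
import pandas as pd
import pytest
from scipy import special

from phyllocore import core_partition as cp
from phyllocore.io_prep import HABITATS, AbundanceTable, SampleMetadata


def _meta(n_per_hab=5):
    rows = []
    for hab in HABITATS:
        for i in range(n_per_hab):
            rows.append(
                {
                    "sample_id": f"{hab}{i}",
                    "habitat": hab,
                    "site": "A",
                    "plot": f"A{i}",
                    "pH": 5.0,
                    "elevation": 100.0,
                }
            )
    return SampleMetadata(pd.DataFrame(rows).set_index("sample_id"))


def _table(columns: dict, meta: SampleMetadata) -> AbundanceTable:
    return AbundanceTable(
        pd.DataFrame(columns, index=meta.data.index, dtype=float), mode="counts"
    )


class TestHabitatOverlap:
    def test_presence_patterns(self):
        meta = _meta()
        hab = meta.data["habitat"]
        tab = _table(
            {
                "soil_only": (hab == "soil") * 3.0,
                "litter_soil": hab.isin(["litter", "soil"]) * 2.0,
                "everywhere": 1.0,
            },
            meta,
        )
        res = cp.habitat_overlap(tab, meta)
        assert res.categories["soil_only"] == "soil"
        assert res.categories["litter_soil"] == "litter+soil"
        assert res.categories["everywhere"] == "all three"

    def test_absent_taxon_excluded_with_warning(self):
        meta = _meta()
        tab = _table({"ghost": 0.0, "real": 1.0}, meta)
        with pytest.warns(UserWarning, match="ghost"):
            res = cp.habitat_overlap(tab, meta)
        assert "ghost" not in res.categories.index


class TestDetectCore:
    def _boundary_table(self, meta):
        # filler dominates; "edge" sits at exactly 0.1% mean RA in host samples
        host = meta.data["habitat"] == "sphagnum"
        edge = np.where(host, 1.0, 0.0)
        edge[np.where(host)[0][0]] = 0.0  # 4/5 host samples = 80% prevalence
        filler = np.where(host & (edge > 0), 999.0, 1000.0)
        # host rows: edge 1 of total 1000 -> RA 0.001 in 4 samples, 0 in one
        return AbundanceTable(
            pd.DataFrame({"edge": edge * 1.0, "filler": filler}, index=meta.data.index),
            mode="counts",
        )

    def test_inclusive_thresholds_at_paper_values(self):
        meta = _meta()
        tab = self._boundary_table(meta)
        # mean RA = 4*0.001/5 = 0.0008 < 0.001 -> adjust min_ra to the mean
        flags = cp.detect_core(tab, meta, min_ra=0.0008, min_prev=0.8)
        assert bool(flags["edge"])
        assert not cp.detect_core(tab, meta, min_ra=0.00081, min_prev=0.8)["edge"]
        assert not cp.detect_core(tab, meta, min_ra=0.0008, min_prev=0.81)["edge"]

    def test_exact_tenth_percent_and_eighty_prevalence(self):
        meta = _meta()
        host = meta.data["habitat"] == "sphagnum"
        edge = np.where(host, 1.0, 0.0)
        edge[np.where(host)[0][0]] = 0.0
        # scale so the MEAN host RA is exactly 0.001: 4 samples at 1/800, one at 0
        filler = np.where(host & (edge > 0), 799.0, 800.0)
        tab = AbundanceTable(
            pd.DataFrame({"edge": edge, "filler": filler}, index=meta.data.index),
            mode="counts",
        )
        flags = cp.detect_core(tab, meta, min_ra=0.001, min_prev=0.8)
        assert bool(flags["edge"])

    def test_high_abundance_low_prevalence_rejected(self):
        meta = _meta()
        host = meta.data["habitat"] == "sphagnum"
        taxon = np.where(host, 500.0, 0.0)
        taxon[np.where(host)[0][:2]] = 0.0  # 3/5 = 60% prevalence
        tab = AbundanceTable(
            pd.DataFrame({"t": taxon, "filler": 1000.0}, index=meta.data.index),
            mode="counts",
        )
        assert not cp.detect_core(tab, meta)["t"]

    def test_monotone_in_both_thresholds(self):
        meta = _meta()
        rng = np.random.default_rng(0)
        tab = AbundanceTable(
            pd.DataFrame(
                rng.integers(0, 50, size=(15, 12)).astype(float),
                index=meta.data.index,
                columns=[f"t{j}" for j in range(12)],
            ),
            mode="counts",
        )
        base = cp.detect_core(tab, meta, min_ra=0.01, min_prev=0.5)
        assert not (cp.detect_core(tab, meta, min_ra=0.02, min_prev=0.5) & ~base).any()
        assert not (cp.detect_core(tab, meta, min_ra=0.01, min_prev=0.7) & ~base).any()


def _sim_zib(rng, n, mu, pi, phi=15.0):
    y = rng.beta(mu * phi, (1 - mu) * phi, n)
    y[rng.random(n) < pi] = 0.0
    return y


class TestFitZib:
    def test_parameter_recovery_within_3se(self):
        hits = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = np.concatenate(
                [
                    _sim_zib(rng, 50, special.expit(0.0), 0.2),
                    _sim_zib(rng, 50, special.expit(-1.5), 0.2),
                ]
            )
            groups = np.array(["host"] * 50 + ["other"] * 50)
            fit = cp.fit_zib(y, groups)
            con = cp.zib_contrasts(fit, "host", ["other"])
            est, z = con["estimate"].iloc[0], con["z"].iloc[0]
            hits.append(abs(est - 1.5) < 3 * abs(est / z))
        assert np.mean(hits) >= 0.9

    def test_loglik_not_below_null_fit(self):
        rng = np.random.default_rng(4)
        y = np.concatenate([_sim_zib(rng, 30, 0.3, 0.2), _sim_zib(rng, 30, 0.6, 0.3)])
        groups = np.array(["a"] * 30 + ["b"] * 30)
        full = cp.fit_zib(y, groups)
        null = cp.fit_zib(y, np.array(["x"] * 60))
        assert full.loglik >= null.loglik - 1e-6

    def test_all_zero_group_flagged_degenerate(self):
        rng = np.random.default_rng(5)
        y = np.concatenate([np.zeros(10), _sim_zib(rng, 10, 0.4, 0.1)])
        groups = np.array(["dead"] * 10 + ["alive"] * 10)
        fit = cp.fit_zib(y, groups)
        assert fit.degenerate_groups == ["dead"]
        assert fit.pi["dead"] == 1.0
        con = cp.zib_contrasts(fit, "alive", ["dead"])
        assert np.isnan(con["p_raw"].iloc[0])

    def test_pi_is_closed_form_zero_fraction(self):
        rng = np.random.default_rng(6)
        y = _sim_zib(rng, 40, 0.5, 0.25)
        fit = cp.fit_zib(y, np.array(["g"] * 40))
        assert fit.pi["g"] == pytest.approx((y == 0).mean())


class TestClassifyCore:
    def test_host_unique_and_environmental_trivial_cases(self):
        meta = _meta(6)
        hab = meta.data["habitat"]
        tab = _table(
            {
                "su_like": (hab == "sphagnum") * 50.0,
                "ec_like": 40.0,
                "filler": 1000.0,
            },
            meta,
        )
        flags = pd.Series(True, index=tab.taxon_ids)
        flags["filler"] = True
        res = cp.classify_core(tab, meta, flags)
        assert res.labels["su_like"] == "SU"
        assert res.labels["ec_like"] == "EC"

    def test_labels_partition_core_set(self):
        meta = _meta(6)
        rng = np.random.default_rng(1)
        data = pd.DataFrame(
            rng.integers(0, 60, size=(18, 8)).astype(float),
            index=meta.data.index,
            columns=[f"t{j}" for j in range(8)],
        )
        tab = AbundanceTable(data + 1.0, mode="counts")  # everything present
        flags = pd.Series(True, index=tab.taxon_ids)
        res = cp.classify_core(tab, meta, flags)
        assert set(res.labels.unique()) <= {"SU", "ES", "EC", "core-unresolved"}


class TestGroupAbundance:
    def _classification(self):
        table = pd.DataFrame(
            {
                "is_core": [True, True, True, False],
                "label": ["SU", "ES", "EC", "non-core"],
            },
            index=["a", "b", "c", "d"],
        )
        return cp.CoreClassification(table)

    def test_manual_oracle(self):
        meta = _meta(1)
        tab = AbundanceTable(
            pd.DataFrame(
                {"a": [2.0, 0, 0], "b": [3.0, 5, 0], "c": [5.0, 5, 5], "d": [0.0, 0, 5]},
                index=meta.data.index,
            ),
            mode="counts",
        )
        cls = self._classification()
        suces = cp.group_abundance(tab, cls, "SU+ES")
        assert suces.iloc[0] == pytest.approx(0.5)  # (2+3)/10
        assert suces.iloc[2] == pytest.approx(0.0)
        total = cp.group_abundance(tab, cls, "total-core")
        assert total.iloc[0] == pytest.approx(1.0)

    def test_share_partition_identity(self):
        meta = _meta(1)
        tab = AbundanceTable(
            pd.DataFrame(
                {"a": [2.0, 1, 1], "b": [3.0, 5, 1], "c": [5.0, 5, 5], "d": [1.0, 0, 5]},
                index=meta.data.index,
            ),
            mode="counts",
        )
        shares = cp.core_shares(tab, self._classification())
        assert shares["count_share"].sum() == pytest.approx(1.0)
        assert shares["abundance_share"].sum() == pytest.approx(1.0)

    def test_empty_group_is_zero(self):
        meta = _meta(1)
        tab = AbundanceTable(
            pd.DataFrame({"a": [2.0, 1, 1], "d": [1.0, 1, 5]}, index=meta.data.index),
            mode="counts",
        )
        table = pd.DataFrame(
            {"is_core": [True, False], "label": ["SU", "non-core"]}, index=["a", "d"]
        )
        ec = cp.group_abundance(tab, cp.CoreClassification(table), "EC")
        assert (ec == 0).all()
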