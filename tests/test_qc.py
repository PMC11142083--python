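"""Variant QC (call rate, MAF, exact HWE) and sample exclusions."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from famscan import GenotypeMatrix, apply_t2d_exclusions, apply_variant_qc, hwe_exact_p


def brute_force_hwe_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Independent oracle: enumerate every genotype configuration with the
    observed allele counts and sum probabilities <= that of the observed
    heterozygote count."""
    n = n_aa + n_ab + n_bb
    rare = 2 * min(n_aa, n_bb) + n_ab
    probs = {}
    for het in range(rare % 2, rare + 1, 2):
        hom_rare = (rare - het) // 2
        hom_common = n - het - hom_rare
        if hom_common < 0:
            continue
        logp = (
            math.lgamma(n + 1)
            - math.lgamma(het + 1)
            - math.lgamma(hom_rare + 1)
            - math.lgamma(hom_common + 1)
            + het * math.log(2)
            + math.lgamma(rare + 1)
            + math.lgamma(2 * n - rare + 1)
            - math.lgamma(2 * n + 1)
        )
        probs[het] = math.exp(logp)
    total = sum(probs.values())
    p_obs = probs[n_ab] / total
    return sum(p / total for p in probs.values() if p / total <= p_obs * (1 + 1e-12))


class TestHWE:
    def test_perfect_proportions_not_rejected(self):
        # (AA=25, Aa=50, aa=25) is exact Hardy-Weinberg; p is of order 1
        assert hwe_exact_p(25, 50, 25) > 0.5

    def test_extreme_het_deficit_rejected(self):
        # enumeration oracle confirms the tail mass is < 1e-6
        p = hwe_exact_p(90, 0, 10)
        assert p < 1e-6
        assert p == pytest.approx(brute_force_hwe_p(90, 0, 10), rel=1e-9)

    @pytest.mark.parametrize(
        "counts",
        [(25, 50, 25), (40, 20, 40), (5, 10, 85), (0, 10, 90), (50, 0, 50), (99, 1, 0)],
    )
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_p(*counts) == pytest.approx(brute_force_hwe_p(*counts), rel=1e-9)


def _matrix(dosages, ids=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(m)],
            "chrom": "1",
            "pos": np.arange(1, m + 1),
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeMatrix(
        ids=ids or [f"i{k}" for k in range(n)], variants=variants, dosages=dosages
    )


class TestVariantQC:
    def test_low_maf_removed_with_reason(self):
        rng = np.random.default_rng(0)
        common = rng.binomial(2, 0.3, size=500).astype(float)
        rare = np.zeros(500)
        rare[:5] = 1.0  # MAF = 0.005
        g = _matrix(np.column_stack([common, rare]))
        filtered, report = apply_variant_qc(g)
        assert filtered.n_variants == 1
        row = report.set_index("variant_id").loc["v1"]
        assert row["removed"] and row["reason"] == "MAF"

    def test_low_call_rate_removed(self):
        rng = np.random.default_rng(1)
        col = rng.binomial(2, 0.3, size=100).astype(float)
        bad = col.copy()
        bad[:5] = np.nan  # call rate 0.95
        g = _matrix(np.column_stack([col, bad]))
        _, report = apply_variant_qc(g)
        assert report.set_index("variant_id").loc["v1", "reason"] == "call_rate"

    def test_hwe_failure_removed(self):
        col = np.array([0.0] * 90 + [2.0] * 10)
        g = _matrix(np.column_stack([col, np.tile([0.0, 1.0, 2.0, 1.0], 25)]))
        _, report = apply_variant_qc(g)
        row = report.set_index("variant_id").loc["v0"]
        assert row["removed"] and "HWE" in row["reason"]

    def test_monomorphic_removed_under_maf_not_error(self):
        g = _matrix(np.column_stack([np.zeros(50), np.tile([0.0, 1.0], 25)]))
        filtered, report = apply_variant_qc(g)
        assert filtered.n_variants == 1
        assert "MAF" in report.set_index("variant_id").loc["v0", "reason"]

    def test_empty_matrix_is_error(self):
        g = _matrix(np.zeros((5, 1)))
        g2 = g.subset_variants(np.array([False]))
        with pytest.raises(ValueError):
            apply_variant_qc(g2)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        dos = rng.binomial(2, rng.uniform(0.005, 0.4, size=8), size=(300, 8)).astype(float)
        g = _matrix(dos)
        once, _ = apply_variant_qc(g)
        twice, rep2 = apply_variant_qc(once)
        assert twice.n_variants == once.n_variants
        assert not rep2["removed"].any()


class TestT2DExclusions:
    def _table(self, **kw):
        base = {
            "id": ["s1"],
            "t2d_diagnosis": [False],
            "t2d_treatment": [False],
            "fasting_glucose": [90.0],
            "hba1c": [5.5],
        }
        base.update({k: [v] for k, v in kw.items()})
        return pd.DataFrame(base)

    @pytest.mark.parametrize(
        "kw,reason",
        [
            ({"hba1c": 6.5}, "hba1c"),
            ({"fasting_glucose": 126.0}, "fasting_glucose"),
            ({"t2d_diagnosis": True}, "t2d_diagnosis"),
            ({"t2d_treatment": True}, "t2d_treatment"),
        ],
    )
    def test_exclusion_rules_fire_at_thresholds(self, kw, reason):
        retained, log = apply_t2d_exclusions(self._table(**kw))
        assert retained == []
        assert reason in log.loc[0, "reason"]

    def test_strict_boundary_retained(self):
        retained, log = apply_t2d_exclusions(
            self._table(hba1c=6.49, fasting_glucose=125.9)
        )
        assert retained == ["s1"]
        assert not log.loc[0, "excluded"]

    def test_missing_values_non_exclusionary_but_logged(self):
        retained, log = apply_t2d_exclusions(self._table(fasting_glucose=np.nan))
        assert retained == ["s1"]
        assert "fasting_glucose missing" in log.loc[0, "note"]

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            apply_t2d_exclusions(self._table(hba1c=-1.0))

    def test_idempotent(self):
        table = pd.DataFrame(
            {
                "id": ["a", "b", "c"],
                "t2d_diagnosis": [False, True, False],
                "t2d_treatment": [False, False, False],
                "fasting_glucose": [100.0, 90.0, 130.0],
                "hba1c": [5.2, 5.4, 5.6],
            }
        )
        retained, _ = apply_t2d_exclusions(table)
        again, _ = apply_t2d_exclusions(table[table["id"].isin(retained)])
        assert again == retained
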