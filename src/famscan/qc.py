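"""Sample and variant quality control.

Variant filters follow common chip/WGS practice for family studies: variants
are removed when the call rate falls below 98%, the minor allele frequency is
below 1%, or an exact Hardy-Weinberg equilibrium test gives p < 1e-6. Subjects
are excluded from the non-diabetic analysis set when they carry a type 2
diabetes diagnosis or treatment, or show undiagnosed-T2D values (fasting
glucose >= 126 mg/dL or HbA1c >= 6.5%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "GenotypeMatrix",
    "hwe_exact_p",
    "apply_variant_qc",
    "apply_t2d_exclusions",
]


@dataclass
class GenotypeMatrix:
    """Additive allele dosages for individuals x variants.

    ``dosages`` is an (n_individuals, n_variants) float array in [0, 2] with
    NaN marking missing calls (never silently imputed).  ``variants`` holds
    per-variant metadata with columns variant_id, chrom, pos (1-based),
    ref, alt.
    """

    ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.ids), len(self.variants)):
            raise ValueError("dosage shape does not match ids x variants")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0.0) < -1e-9 or np.nanmax(
                self.dosages, initial=0.0
            ) > 2.0 + 1e-9:
                raise ValueError("dosages must lie in [0, 2]")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def maf(self) -> np.ndarray:
        """Folded allele frequency from dosages, in [0, 0.5]."""
        with np.errstate(invalid="ignore"):
            p = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def dosage_of(self, variant_id: str) -> np.ndarray:
        j = self.variants.index[self.variants["variant_id"] == variant_id]
        if len(j) == 0:
            raise KeyError(f"variant {variant_id!r} not found")
        return self.dosages[:, j[0]]

    def subset_variants(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            ids=list(self.ids),
            variants=self.variants.loc[mask].reset_index(drop=True),
            dosages=self.dosages[:, mask],
        )

    def subset_individuals(self, ids) -> "GenotypeMatrix":
        pos = {iid: k for k, iid in enumerate(self.ids)}
        idx = np.array([pos[i] for i in ids], dtype=int)
        return GenotypeMatrix(
            ids=list(ids), variants=self.variants, dosages=self.dosages[idx]
        )


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg test p-value.

    Enumerates all heterozygote counts compatible with the observed allele
    counts and sums the probabilities of configurations no more likely than
    the observed one (two-sided exact test).  Stable for the extreme
    thresholds used in variant QC, where the chi-square approximation is not.
    """
    obs_het = int(n_het)
    n = int(n_hom_ref) + int(n_het) + int(n_hom_alt)
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom_ref, n_hom_alt) + n_het  # rare-allele count
    # P(het = h | allele counts) via log-probabilities from the hypergeometric
    # form: C(n, h) * C(n - h, (rare - h)/2) ... expressed with log-factorials.
    hets = np.arange(rare % 2, rare + 1, 2)
    n_rare_hom = (rare - hets) // 2
    n_common_hom = n - hets - n_rare_hom
    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(n_rare_hom + 1)
        - gammaln(n_common_hom + 1)
        + hets * np.log(2.0)
        + gammaln(rare + 1)
        + gammaln(2 * n - rare + 1)
        - gammaln(2 * n + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    p_obs = prob[hets == obs_het]
    if len(p_obs) == 0:
        raise ValueError("heterozygote count incompatible with allele counts")
    return float(min(1.0, prob[prob <= p_obs[0] * (1.0 + 1e-12)].sum()))


def _hard_calls(dosages: np.ndarray) -> np.ndarray:
    """Round dosages to hard genotype calls (nearest integer, ties-to-even)."""
    return np.rint(dosages)


def apply_variant_qc(
    g: GenotypeMatrix,
    min_call_rate: float = 0.98,
    min_maf: float = 0.01,
    min_hwe_p: float = 1e-6,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Filter variants by call rate, MAF and exact HWE.

    Returns the filtered matrix and a per-variant report with columns
    variant_id, call_rate, maf, hwe_p, removed, reason (all failing rules
    listed, semicolon-separated).  Monomorphic variants fall under the MAF
    rule.  The HWE test uses hard calls obtained by ties-to-even rounding of
    the dosages; intermediate dosages are rounded, not set missing.
    """
    if g.n_variants == 0:
        raise ValueError("empty genotype matrix")
    call_rate = g.call_rate()
    maf = g.maf()
    hard = _hard_calls(g.dosages)
    hwe_p = np.ones(g.n_variants)
    for j in range(g.n_variants):
        col = hard[:, j]
        col = col[~np.isnan(col)]
        if len(col) == 0:
            hwe_p[j] = 1.0
            continue
        hwe_p[j] = hwe_exact_p(
            int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
        )
    reasons = []
    for j in range(g.n_variants):
        r = []
        if call_rate[j] < min_call_rate:
            r.append("call_rate")
        if maf[j] < min_maf or np.isnan(maf[j]):
            r.append("MAF")
        if hwe_p[j] < min_hwe_p:
            r.append("HWE")
        reasons.append(";".join(r))
    report = pd.DataFrame(
        {
            "variant_id": g.variants["variant_id"],
            "call_rate": call_rate,
            "maf": maf,
            "hwe_p": hwe_p,
            "removed": [bool(r) for r in reasons],
            "reason": reasons,
        }
    )
    keep = ~report["removed"].to_numpy()
    return g.subset_variants(keep), report


def apply_t2d_exclusions(
    table: pd.DataFrame,
    glucose_threshold: float = 126.0,
    hba1c_threshold: float = 6.5,
) -> tuple[list[str], pd.DataFrame]:
    """Exclude subjects with diagnosed or undiagnosed type 2 diabetes.

    ``table`` needs columns id, t2d_diagnosis, t2d_treatment,
    fasting_glucose (mg/dL), hba1c (percent).  A subject is excluded iff
    diagnosed, treated, fasting glucose >= 126 mg/dL, or HbA1c >= 6.5%.
    Missing values are non-exclusionary and noted in the log.  Returns the
    retained id list and a per-subject log recording which rule fired.
    """
    required = {"id", "t2d_diagnosis", "t2d_treatment", "fasting_glucose", "hba1c"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise ValueError(f"missing columns: {sorted(missing_cols)}")
    fg = pd.to_numeric(table["fasting_glucose"], errors="coerce")
    a1c = pd.to_numeric(table["hba1c"], errors="coerce")
    if (fg.dropna() < 0).any() or (a1c.dropna() < 0).any():
        raise ValueError("negative fasting glucose or HbA1c")
    diag = table["t2d_diagnosis"].fillna(False).astype(bool)
    treat = table["t2d_treatment"].fillna(False).astype(bool)
    rows = []
    retained: list[str] = []
    for k in range(len(table)):
        reasons = []
        if diag.iloc[k]:
            reasons.append("t2d_diagnosis")
        if treat.iloc[k]:
            reasons.append("t2d_treatment")
        if not np.isnan(fg.iloc[k]) and fg.iloc[k] >= glucose_threshold:
            reasons.append("fasting_glucose")
        if not np.isnan(a1c.iloc[k]) and a1c.iloc[k] >= hba1c_threshold:
            reasons.append("hba1c")
        notes = []
        if np.isnan(fg.iloc[k]):
            notes.append("fasting_glucose missing")
        if np.isnan(a1c.iloc[k]):
            notes.append("hba1c missing")
        excluded = bool(reasons)
        if not excluded:
            retained.append(str(table["id"].iloc[k]))
        rows.append(
            {
                "id": str(table["id"].iloc[k]),
                "excluded": excluded,
                "reason": ";".join(reasons),
                "note": ";".join(notes),
            }
        )
    return retained, pd.DataFrame(rows)
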