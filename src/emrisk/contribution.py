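"""Perturbation-based relative-contribution (RC) analysis.

Given a trained risk model and a labeled cohort, each feature's influence is
measured by occlusion: for every occurrence of the feature token in a
patient's sequence, the predicted risk is recomputed with that single
occurrence masked to the padding id, and the drop

    delta = P(case | original) - P(case | occurrence masked)

is summed over the feature's occurrences within the patient to give the raw
feature contribution (FC). Each patient's FC vector is then normalized by
the sum of absolute contributions over all of that patient's features, which
removes the dependence on healthcare-utilization volume (patients with many
encounters would otherwise dominate).

The relative contribution of a feature is the ratio of its mean normalized
FC among cases (m patients) to the mean among controls (n patients):

    RC = mean(FC | case) / mean(FC | control)

with a delta-method variance on the log scale built from the two groups'
squared coefficients of variation,

    Var(ln RC) = (sd_case/mean_case)^2 / m + (sd_control/mean_control)^2 / n

a normal-approximation 95% CI, exp(ln RC +- 1.96 sqrt(Var)), and a
two-sided z-test of ln RC = 0. Bonferroni and Benjamini-Hochberg FDR
corrections are applied across features, and finally all RCs are rescaled so
that a designated reference feature (conventionally the cohort-defining
PTSD diagnosis group, present in nearly every record) has RC exactly 1.

RC > 1 flags risk features, RC < 1 protective ones. The ratio is only
meaningful when the two group means share a sign (masking a protective
feature *raises* predicted risk, so protective features have negative means
in both groups); features with opposite-sign or zero group means are flagged
indeterminate and excluded from inference.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import EncodedDataset

logger = logging.getLogger(__name__)

Z_95 = 1.96  # conventional two-sided 95% normal quantile


# ---------------------------------------------------------------------------
# per-patient feature contributions
# ---------------------------------------------------------------------------

def feature_contribution(model, encoded: EncodedDataset, sample_index: int,
                         feature_id: int) -> float:
    """Raw FC of one feature for one patient: sum of per-occurrence deltas.

    Zero when the feature does not occur in the sample; a constant model
    yields zero for every feature.
    """
    fc = occlusion_contributions(model, encoded, sample_index)
    return float(fc.get(feature_id, 0.0))


def occlusion_contributions(model, encoded: EncodedDataset, sample_index: int) -> dict[int, float]:
    """Raw FC for every feature occurring in one patient's sequence.

    Builds one batch holding the original sequence plus one copy per token
    occurrence with that occurrence masked to the padding id, then sums the
    per-occurrence prediction drops by feature id.
    """
    ids = encoded.ids[sample_index]
    gaps = encoded.gaps[sample_index]
    vmask = encoded.visit_mask[sample_index]
    positions = np.argwhere(ids > 0)
    if positions.size == 0:
        return {}
    batch = np.broadcast_to(ids, (len(positions) + 1, *ids.shape)).copy()
    for k, (t, l) in enumerate(positions, start=1):
        batch[k, t, l] = 0
    g = np.broadcast_to(gaps, (len(batch), *gaps.shape))
    m = np.broadcast_to(vmask, (len(batch), *vmask.shape))
    probs = model.predict_encoded(batch, g, m)
    deltas = probs[0] - probs[1:]
    fc: dict[int, float] = {}
    for (t, l), d in zip(positions, deltas):
        fid = int(ids[t, l])
        fc[fid] = fc.get(fid, 0.0) + float(d)
    return fc


def normalize_fc(raw_fc: dict[int, float] | np.ndarray):
    """Normalize one patient's raw FC vector by its sum of absolute values.

    Signs are preserved; an all-zero vector passes through unchanged.
    """
    if isinstance(raw_fc, dict):
        denom = sum(abs(v) for v in raw_fc.values())
        if denom == 0:
            return dict(raw_fc)
        return {k: v / denom for k, v in raw_fc.items()}
    raw_fc = np.asarray(raw_fc, dtype=float)
    denom = np.abs(raw_fc).sum()
    return raw_fc if denom == 0 else raw_fc / denom


def contribution_matrix(model, encoded: EncodedDataset) -> pd.DataFrame:
    """Normalized FC matrix: rows = patients, columns = feature ids.

    Features absent from a patient contribute 0; features absent from every
    patient do not appear at all.
    """
    rows = []
    for i in range(len(encoded)):
        rows.append(normalize_fc(occlusion_contributions(model, encoded, i)))
    matrix = pd.DataFrame(rows, index=encoded.patient_ids).fillna(0.0)
    matrix = matrix[sorted(matrix.columns)]
    matrix.insert(0, "__label__", encoded.labels)
    return matrix


# ---------------------------------------------------------------------------
# RC inference
# ---------------------------------------------------------------------------

def relative_contribution(fc_cases, fc_controls) -> float:
    """RC = mean FC among cases / mean FC among controls.

    Raises ValueError when the group means do not share a sign (the ratio
    is then not interpretable as a positive relative contribution).
    """
    mc = float(np.mean(fc_cases))
    mn = float(np.mean(fc_controls))
    if mc * mn <= 0:
        raise ValueError("group mean FCs must share a sign (indeterminate feature)")
    return mc / mn


def variance_ln_rc(fc_cases, fc_controls) -> float:
    """Delta-method variance of ln RC from the two groups' squared CVs."""
    fc_cases = np.asarray(fc_cases, dtype=float)
    fc_controls = np.asarray(fc_controls, dtype=float)
    m, n = len(fc_cases), len(fc_controls)
    if m < 2 or n < 2:
        raise ValueError("each group needs >= 2 patients for a sample sd")
    mc, mn = fc_cases.mean(), fc_controls.mean()
    if mc == 0 or mn == 0:
        raise ValueError("zero group mean FC (indeterminate feature)")
    return float((fc_cases.std(ddof=1) / mc) ** 2 / m
                 + (fc_controls.std(ddof=1) / mn) ** 2 / n)


def ci_rc(rc: float, var_ln_rc: float, level: float = 0.95) -> tuple[float, float]:
    """Exponentiated normal interval on ln RC (1.96 at the 95% level)."""
    if rc <= 0 or var_ln_rc < 0:
        raise ValueError("rc must be positive and var_ln_rc non-negative")
    z = Z_95 if level == 0.95 else float(stats.norm.ppf(0.5 + level / 2))
    half = z * np.sqrt(var_ln_rc)
    return float(np.exp(np.log(rc) - half)), float(np.exp(np.log(rc) + half))


def p_value(rc: float, var_ln_rc: float) -> float:
    """Two-sided z-test of ln RC = 0: p = 2 * (1 - Phi(|ln RC| / sqrt(Var)))."""
    if rc <= 0:
        raise ValueError("rc must be positive")
    if var_ln_rc == 0:
        if rc != 1.0:
            warnings.warn("zero variance with RC != 1; reporting p = 0")
            return 0.0
        return 1.0
    z = abs(np.log(rc)) / np.sqrt(var_ln_rc)
    return float(2.0 * stats.norm.sf(z))


def adjust_bonferroni(p_values) -> np.ndarray:
    """Bonferroni family-wise correction: p * k, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="bonferroni")[1]


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def scale_rc(table: pd.DataFrame, reference_feature: str) -> pd.DataFrame:
    """Rescale all RCs (and CI bounds) so the reference feature's RC is 1.

    The common factor 1/RC(reference) preserves every between-feature RC
    ratio; p-values and variances are scale-free and unchanged.
    """
    ref = table.loc[table["feature"] == reference_feature]
    if ref.empty:
        raise ValueError(f"reference feature {reference_feature!r} not in the RC table")
    ref_rc = float(ref["rc"].iloc[0])
    if ref_rc <= 0:
        raise ValueError("reference feature must have a positive RC")
    factor = 1.0 / ref_rc
    out = table.copy()
    out["rc_scaled"] = out["rc"] * factor
    out["ci95_low_scaled"] = out["ci95_low"] * factor
    out["ci95_high_scaled"] = out["ci95_high"] * factor
    return out


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

def rc_table(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """RC inference for every feature column of a normalized FC matrix.

    Returns (tested, indeterminate): tested features carry rc, var_ln_rc,
    CI bounds, p and both multiple-testing corrections; indeterminate ones
    (opposite-sign or zero group means, or a degenerate group) are listed
    separately and never enter the corrections.
    """
    labels = matrix["__label__"].to_numpy()
    features = [c for c in matrix.columns if c != "__label__"]
    case_rows = labels == 1
    rows, indeterminate = [], []
    for feat in features:
        fc = matrix[feat].to_numpy(dtype=float)
        fc_cases, fc_controls = fc[case_rows], fc[~case_rows]
        try:
            rc = relative_contribution(fc_cases, fc_controls)
            var = variance_ln_rc(fc_cases, fc_controls)
        except ValueError as err:
            indeterminate.append({"feature": feat, "reason": str(err)})
            logger.info("feature %s indeterminate: %s", feat, err)
            continue
        lo, hi = ci_rc(rc, var)
        rows.append({
            "feature": feat, "rc": rc, "var_ln_rc": var,
            "ci95_low": lo, "ci95_high": hi, "p": p_value(rc, var),
            "m_cases": int(case_rows.sum()), "n_controls": int((~case_rows).sum()),
        })
    tested = pd.DataFrame(rows)
    if len(tested):
        tested["p_bonferroni"] = adjust_bonferroni(tested["p"].to_numpy())
        tested["q_fdr"] = adjust_fdr(tested["p"].to_numpy())
    return tested, pd.DataFrame(indeterminate)


def contribution_report(
    model,
    encoded: EncodedDataset,
    vocabulary,
    reference_feature: str,
    token_channels: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """End-to-end RC report for a trained model on a labeled dataset.

    Computes occlusion contributions for every (patient, feature) pair,
    normalizes per patient, runs RC inference per feature, applies
    Bonferroni and BH-FDR corrections, rescales to the reference feature,
    and returns rows sorted by Bonferroni-corrected p. The second return
    value lists indeterminate features.
    """
    if case_control_counts(encoded) == (0, 0):
        raise ValueError("dataset has no labeled patients")
    matrix = contribution_matrix(model, encoded)
    tested, indeterminate = rc_table(matrix)
    if tested.empty:
        raise ValueError("no feature admitted RC inference")
    tested["feature"] = [vocabulary.decode(int(f)) for f in tested["feature"]]
    if not indeterminate.empty:
        indeterminate["feature"] = [vocabulary.decode(int(f)) for f in indeterminate["feature"]]
    if token_channels:
        tested.insert(1, "channel", tested["feature"].map(token_channels).fillna(""))
    tested = scale_rc(tested, reference_feature)
    tested = tested.sort_values(["p_bonferroni", "p", "feature"]).reset_index(drop=True)
    return tested, indeterminate


def case_control_counts(encoded: EncodedDataset) -> tuple[int, int]:
    return int((encoded.labels == 1).sum()), int((encoded.labels == 0).sum())


def fc_group_summary(matrix: pd.DataFrame, vocabulary, features=None) -> pd.DataFrame:
    """Mean +- sd of normalized FC per feature (cases vs controls).

    Companion view for features reported descriptively rather than as RC
    ratios (used for the SDoH table shape).
    """
    labels = matrix["__label__"].to_numpy()
    cols = [c for c in matrix.columns if c != "__label__"]
    rows = []
    for feat in cols:
        name = vocabulary.decode(int(feat))
        if features is not None and name not in features:
            continue
        fc = matrix[feat].to_numpy(dtype=float)
        rows.append({
            "feature": name,
            "mean": fc.mean(), "sd": fc.std(ddof=1),
            "mean_cases": fc[labels == 1].mean(), "mean_controls": fc[labels == 0].mean(),
        })
    return pd.DataFrame(rows)
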