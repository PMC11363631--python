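"""Relative qPCR expression by the comparative-Ct (2^-ddCt) method with
technical-replicate QC and normality-gated two-group comparisons.

Workflow: technical replicates (triplicates) are screened for outliers
and averaged; dCt = Ct_target - Ct_reference per sample; ddCt subtracts
the calibrator sample's dCt (by default the sample with the lowest dCt,
i.e. the highest expresser, so every relative quantity RQ = 2^-ddCt lies
in (0, 1] with the calibrator at exactly 1); group comparisons use a
two-tailed t-test when both groups pass Shapiro-Wilk normality and have
at least 8 samples, and the two-sided Mann-Whitney U otherwise.

Replicate QC: the stated "2 standard deviations" screen cannot operate
within a triplicate (no point of a sample of three can lie more than
2/sqrt(3) sample SDs from its own mean), so the rule is applied in
leave-one-out form: a replicate is an outlier when it deviates from the
mean of its sibling replicates by more than max(2 x SD(siblings),
``min_dev``).  The absolute floor (default 0.5 cycles, a conventional
qPCR replicate tolerance) keeps ultra-tight triplicates from being
flagged on sub-noise differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

ALPHA_DEFAULT = 0.05
MIN_N_NORMALITY = 8


@dataclass
class QCResult:
    retained: np.ndarray
    removed_index: list[int]
    usable: bool
    mean_ct: float


def replicate_qc(
    cts: Sequence[float], n_sd: float = 2.0, min_dev: float = 0.5
) -> QCResult:
    """Screen one sample's technical replicates for outliers.

    One replicate (the most deviant) may be removed per pass; the check
    is repeated once on the survivors if at least three remain.  Fewer
    than two retained replicates marks the sample unusable.
    """
    values = np.asarray(list(cts), dtype=float)
    if values.size < 2:
        raise ValueError("replicate QC needs at least 2 replicates")
    keep = np.ones(values.size, dtype=bool)
    removed: list[int] = []

    for _ in range(2):  # initial pass + one re-check after removal
        idx = np.nonzero(keep)[0]
        if idx.size < 3:
            break
        devs = np.empty(idx.size)
        thr = np.empty(idx.size)
        for j, i in enumerate(idx):
            others = values[idx[idx != i]]
            devs[j] = abs(values[i] - others.mean())
            thr[j] = max(n_sd * others.std(ddof=1), min_dev)
        excess = devs - thr
        worst = int(np.argmax(excess))
        if excess[worst] > 0:
            keep[idx[worst]] = False
            removed.append(int(idx[worst]))
        else:
            break

    retained = values[keep]
    return QCResult(
        retained=retained,
        removed_index=removed,
        usable=retained.size >= 2,
        mean_ct=float(retained.mean()) if retained.size else float("nan"),
    )


class ExpressionError(ValueError):
    pass


def _qc_mean_table(ct: pd.DataFrame, n_sd: float, min_dev: float) -> pd.DataFrame:
    """Per (sample, gene, tissue): QC'd mean Ct plus usability flag."""
    rows = []
    keys = ["sample_id", "tissue", "gene"]
    meta = [c for c in ("strain", "timepoint") if c in ct.columns]
    for key, grp in ct.groupby(keys, sort=True):
        qc = replicate_qc(grp["Ct"].to_numpy(), n_sd=n_sd, min_dev=min_dev)
        rows.append(
            list(key)
            + [grp[m].iloc[0] for m in meta]
            + [qc.mean_ct, qc.usable, len(qc.removed_index)]
        )
    return pd.DataFrame(rows, columns=keys + meta + ["ct_mean", "usable", "n_removed"])


def delta_delta_ct(
    ct: pd.DataFrame,
    target_gene: str,
    reference_gene: str = "ef1a",
    calibrator: str = "lowest-dct",
    n_sd: float = 2.0,
    min_dev: float = 0.5,
) -> pd.DataFrame:
    """Per-sample relative quantities RQ = 2^-ddCt for one target gene.

    Parameters
    ----------
    ct : DataFrame
        Long Ct table with columns ``sample_id, tissue, gene, replicate,
        Ct`` (plus optional ``strain``/``timepoint`` carried through).
    calibrator : str
        ``"lowest-dct"`` (default; the highest-expressing sample),
        ``"lowest-ct"`` (literal lowest raw target Ct), or an explicit
        sample id.

    Samples lacking a usable reference- or target-gene Ct are excluded;
    the number excluded is recorded in ``result.attrs['n_excluded']``.
    """
    if target_gene == reference_gene:
        raise ExpressionError("target and reference gene must differ")
    means = _qc_mean_table(ct[ct["gene"].isin([target_gene, reference_gene])], n_sd, min_dev)
    meta = [c for c in ("strain", "timepoint") if c in means.columns]
    usable = means[means["usable"]]
    wide = usable.pivot_table(
        index=["sample_id", "tissue"] + meta, columns="gene", values="ct_mean"
    ).reset_index()
    n_before = wide.shape[0]
    if reference_gene not in wide.columns:
        raise ExpressionError(f"reference gene {reference_gene!r} absent from table")
    if target_gene not in wide.columns:
        raise ExpressionError(f"target gene {target_gene!r} absent from table")
    wide = wide.dropna(subset=[reference_gene, target_gene]).reset_index(drop=True)

    out_frames = []
    for tissue, sub in wide.groupby("tissue", sort=True):
        sub = sub.copy()
        sub["dct"] = sub[target_gene] - sub[reference_gene]
        if calibrator == "lowest-dct":
            cal_row = sub.loc[sub["dct"].idxmin()]
        elif calibrator == "lowest-ct":
            cal_row = sub.loc[sub[target_gene].idxmin()]
        else:
            match = sub[sub["sample_id"] == calibrator]
            if match.empty:
                raise ExpressionError(
                    f"calibrator sample {calibrator!r} not found for tissue {tissue!r}"
                )
            cal_row = match.iloc[0]
        sub["ddct"] = sub["dct"] - cal_row["dct"]
        sub["rq"] = np.power(2.0, -sub["ddct"])
        sub["calibrator"] = cal_row["sample_id"]
        sub["gene"] = target_gene
        out_frames.append(sub)

    result = pd.concat(out_frames, ignore_index=True)[
        ["sample_id", "tissue", "gene"] + meta + ["dct", "ddct", "rq", "calibrator"]
    ]
    result.attrs["n_excluded"] = n_before - len(result)
    return result


@dataclass(frozen=True)
class Verdict:
    """Outcome of a two-group comparison, recording the path taken."""

    test: str  # "t-test" | "mann-whitney" | "insufficient data"
    statistic: float
    p_value: float
    significant: bool
    n1: int
    n2: int
    shapiro_p: tuple[float, float] | None = None
    reason: str = ""


def compare_groups(
    group1: Sequence[float],
    group2: Sequence[float],
    alpha: float = ALPHA_DEFAULT,
    min_n_normality: int = MIN_N_NORMALITY,
    welch: bool = False,
) -> Verdict:
    """Normality-gated two-group comparison.

    Either group below ``min_n_normality`` samples goes straight to the
    two-sided Mann-Whitney U; otherwise both groups face Shapiro-Wilk at
    alpha, and only a double pass earns the two-tailed t-test (Student's
    by default, Welch behind the flag).
    """
    x = np.asarray(list(group1), dtype=float)
    y = np.asarray(list(group2), dtype=float)
    if x.size < 2 or y.size < 2:
        return Verdict(
            test="insufficient data",
            statistic=float("nan"),
            p_value=float("nan"),
            significant=False,
            n1=x.size,
            n2=y.size,
            reason="fewer than 2 observations in a group",
        )
    if x.size < min_n_normality or y.size < min_n_normality:
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        return Verdict(
            "mann-whitney", float(stat), float(p), bool(p < alpha), x.size, y.size,
            reason=f"group below n = {min_n_normality}",
        )
    sw1, sw2 = stats.shapiro(x), stats.shapiro(y)
    if sw1.pvalue > alpha and sw2.pvalue > alpha:
        stat, p = stats.ttest_ind(x, y, equal_var=not welch)
        return Verdict(
            "t-test", float(stat), float(p), bool(p < alpha), x.size, y.size,
            shapiro_p=(float(sw1.pvalue), float(sw2.pvalue)),
        )
    stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
    return Verdict(
        "mann-whitney", float(stat), float(p), bool(p < alpha), x.size, y.size,
        shapiro_p=(float(sw1.pvalue), float(sw2.pvalue)),
        reason="normality rejected",
    )


def strain_timepoint_grid(
    ct: pd.DataFrame,
    genes: Sequence[str],
    tissues: Sequence[str] | None = None,
    reference_gene: str = "ef1a",
    scale: str = "rq",
    alpha: float = ALPHA_DEFAULT,
    calibrator: str = "lowest-dct",
    **kwargs,
) -> pd.DataFrame:
    """All four comparisons per gene x tissue over 2 strains x 2 timepoints.

    Emits two between-strain tests (one per timepoint) and two
    between-timepoint tests (one per strain), with letter annotations
    for the strain contrasts (groups sharing a letter do not differ) and
    a star for significant timepoint contrasts.  Comparisons with a
    missing cell are skipped.
    """
    if scale not in ("rq", "dct"):
        raise ExpressionError("scale must be 'rq' or 'dct'")
    tissues = list(tissues) if tissues is not None else sorted(ct["tissue"].unique())
    rows = []
    for gene in genes:
        rq = delta_delta_ct(ct, gene, reference_gene, calibrator=calibrator, **kwargs)
        value = "rq" if scale == "rq" else "dct"
        for tissue in tissues:
            sub = rq[rq["tissue"] == tissue]
            if sub.empty:
                continue
            strains = sorted(sub["strain"].unique())
            tps = sorted(sub["timepoint"].unique())

            def cell(strain, tp):
                return sub[(sub["strain"] == strain) & (sub["timepoint"] == tp)][value].to_numpy()

            for tp in tps:
                if len(strains) == 2:
                    g1, g2 = cell(strains[0], tp), cell(strains[1], tp)
                    if g1.size and g2.size:
                        v = compare_groups(g1, g2, alpha=alpha)
                        rows.append(
                            (gene, tissue, "strain", tp, strains[0], strains[1],
                             v.test, v.statistic, v.p_value, v.significant,
                             "a vs b" if v.significant else "a vs a")
                        )
            for strain in strains:
                if len(tps) == 2:
                    g1, g2 = cell(strain, tps[0]), cell(strain, tps[1])
                    if g1.size and g2.size:
                        v = compare_groups(g1, g2, alpha=alpha)
                        rows.append(
                            (gene, tissue, "timepoint", strain, tps[0], tps[1],
                             v.test, v.statistic, v.p_value, v.significant,
                             "*" if v.significant else "")
                        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "tissue", "contrast", "within", "group1", "group2",
            "test", "statistic", "p_value", "significant", "annotation",
        ],
    )
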