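"""Stage 4: qPCR relative quantification.

Two quantities, both assuming perfect doubling per cycle (efficiency 2.0):

* MNase-qPCR relative nucleosome protection.  Per sample,
  rNP = 2^-[Ct(MNase) - Ct(gDNA)] for a target locus, normalized to the
  same quantity at a control locus with a genotype-invariant nucleosome
  (the *Mwp1* convention).  Because the control-locus normalization is
  itself a second Delta, the reported value equals a 2^-DeltaDeltaCt with
  the control locus playing the reference role.

* qRT-PCR relative expression by 2^-DeltaDeltaCt: per sample,
  DeltaCt = Ct(target) - Ct(reference gene); DeltaDeltaCt subtracts the
  mean DeltaCt of a calibrator genotype, whose mean fold change is 1 by
  construction.

Technical replicates are averaged on the Ct scale before any Delta is
computed.  Group summaries report mean +- SD on the fold-change scale and a
two-sided pooled t test between genotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["target", "sample", "genotype", "assay", "tech_rep", "ct"]
ASSAYS = ("mnase", "gdna", "cdna", "reference_gene")


class MissingAssayError(KeyError):
    pass


def load_ct_csv(path) -> pd.DataFrame:
    ct = pd.read_csv(path)
    missing = set(CT_COLUMNS) - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return validate_ct(ct)


def validate_ct(ct: pd.DataFrame) -> pd.DataFrame:
    if (ct["ct"] <= 0).any():
        bad = ct.loc[ct["ct"] <= 0].iloc[0]
        raise ValueError(
            f"non-positive Ct for target={bad['target']} sample={bad['sample']}"
        )
    return ct


def _mean_ct(ct: pd.DataFrame, target: str, assay: str) -> pd.Series:
    """Technical-replicate-averaged Ct per sample for one (target, assay)."""
    sub = ct[(ct["target"] == target) & (ct["assay"] == assay)]
    if sub.empty:
        raise MissingAssayError(f"no Ct rows for target={target!r} assay={assay!r}")
    return sub.groupby("sample")["ct"].mean()


def _genotype_of(ct: pd.DataFrame) -> pd.Series:
    return ct.drop_duplicates("sample").set_index("sample")["genotype"]


@dataclass
class GroupSummary:
    """Per-genotype mean +- SD of fold values plus a two-group pooled t test."""

    means: dict[str, float]
    sds: dict[str, float]
    t_statistic: float = math.nan
    p_value: float = math.nan
    groups_tested: tuple[str, str] | None = None


def _summarize(per_sample: pd.Series, genotype: pd.Series) -> GroupSummary:
    groups = genotype.loc[per_sample.index]
    means, sds, by = {}, {}, {}
    for g, vals in per_sample.groupby(groups):
        means[g] = float(vals.mean())
        sds[g] = float(vals.std(ddof=1)) if len(vals) > 1 else math.nan
        by[g] = vals.to_numpy()
    summary = GroupSummary(means=means, sds=sds)
    names = sorted(by)
    if len(names) == 2 and all(len(by[g]) >= 2 for g in names):
        t, p = stats.ttest_ind(by[names[0]], by[names[1]], equal_var=True)
        summary.t_statistic, summary.p_value = float(t), float(p)
        summary.groups_tested = (names[0], names[1])
    return summary


@dataclass
class QuantResult:
    per_sample: pd.Series  # fold / relative value per sample id
    summary: GroupSummary


def relative_np(
    ct: pd.DataFrame, target: str, control_locus: str = "Mwp1"
) -> QuantResult:
    """MNase-qPCR relative nucleosome protection, control-locus normalized.

    Per sample: 2^-[Ct_mnase - Ct_gdna] at ``target`` divided by the same
    quantity at ``control_locus``.  Both loci need mnase and gdna assays in
    every sample; a missing assay raises ``MissingAssayError``.
    """
    validate_ct(ct)
    dct_target = _mean_ct(ct, target, "mnase") - _mean_ct(ct, target, "gdna")
    dct_control = _mean_ct(ct, control_locus, "mnase") - _mean_ct(ct, control_locus, "gdna")
    aligned = pd.concat(
        {"target": dct_target, "control": dct_control}, axis=1
    ).dropna()
    if aligned.empty:
        raise MissingAssayError(
            f"no sample has complete mnase+gdna assays for both {target!r} "
            f"and {control_locus!r}"
        )
    rel = np.power(2.0, -(aligned["target"] - aligned["control"]))
    rel.name = f"relative_np[{target}/{control_locus}]"
    return QuantResult(rel, _summarize(rel, _genotype_of(ct)))


def relative_expression(
    ct: pd.DataFrame,
    target: str,
    reference_gene: str,
    calibrator_genotype: str,
    assay: str = "cdna",
) -> QuantResult:
    """qRT-PCR fold change by 2^-DeltaDeltaCt.

    The calibrator genotype's mean DeltaCt defines the baseline, so its
    mean fold change is exactly 1.
    """
    validate_ct(ct)
    dct = _mean_ct(ct, target, assay) - _mean_ct(ct, reference_gene, assay)
    dct = dct.dropna()
    genotype = _genotype_of(ct)
    calib = dct[genotype.loc[dct.index] == calibrator_genotype]
    if calib.empty:
        raise ValueError(f"calibrator group {calibrator_genotype!r} is empty")
    ddct = dct - calib.mean()
    fold = np.power(2.0, -ddct)
    fold.name = f"fold[{target}/{reference_gene} vs {calibrator_genotype}]"
    return QuantResult(fold, _summarize(fold, genotype))
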