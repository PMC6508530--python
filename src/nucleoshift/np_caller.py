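"""Stage 2: call differential nucleosome-position (NP) regions.

Within each analyzable TSS window, every probe is tested twice between the
two genotypes: once on the nucleosomal channel (the MNase log2 ratio, where
a difference means the chromatin changed) and once on the reference channel
(undigested gDNA, where a difference means the DNA itself differs and the
probe must not be trusted).  A probe *qualifies* when the nucleosomal test
is significant (p <= alpha) AND the reference test is not (p > alpha).
Maximal runs of consecutive qualifying probes whose genomic span covers at
least ``min_span`` bp (default 140, just under one nucleosome footprint)
become NP calls, labeled *gain* or *loss* of a positioned nucleosome in the
query genotype by the sign of the mean profile difference over the run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .array_io import ProbeLayout, SignalSet, average_profile
from .polymorphism_filter import RegionMask, ttest_matrix

GAIN = "gain"
LOSS = "loss"


@dataclass
class NPCall:
    """One called differential-NP region (coordinates 1-based inclusive)."""

    window_id: str
    gene_id: str
    call_name: str
    chrom: str
    start: int
    end: int
    direction: str
    probe_ids: list[str]
    nuc_p: np.ndarray
    ref_p: np.ndarray
    mean_delta: float  # mean (query - wild type) nucleosomal signal over run
    zero_tie: bool = False

    @property
    def span_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


def classify_direction(delta: np.ndarray) -> tuple[str, float, bool]:
    """Direction from the mean (query - wild type) signal over run probes.

    gain iff mean > 0; an exact zero mean is tie-broken as loss and flagged.
    """
    delta = np.asarray(delta, dtype=float)
    if delta.size == 0:
        raise ValueError("empty run")
    mean = float(np.nanmean(delta))
    if mean > 0:
        return GAIN, mean, False
    return LOSS, mean, mean == 0.0


def arraywide_correlation(profile_a, profile_b) -> float:
    """Pearson r between two per-probe mean profiles over paired finite values.

    Returns NaN (undefined) when fewer than two pairs remain or either side
    is constant.
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles differ in length")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return math.nan
    return float(stats.pearsonr(a, b)[0])


def call_np_changes(
    wt_nuc: SignalSet,
    q_nuc: SignalSet,
    wt_ref: SignalSet,
    q_ref: SignalSet,
    layout: ProbeLayout,
    mask: RegionMask | None = None,
    alpha: float = 0.05,
    min_span: int = 140,
    max_gap: int | None = None,
    equal_var: bool = True,
) -> list[NPCall]:
    """Call differential NP regions between wild type and query genotype.

    ``max_gap`` is the largest allowed start-to-start distance between
    consecutive probes of a run; the default (the layout's tiling step)
    means a single missing or disqualified tile breaks a run.  Runs are
    maximal; the union span of a run's probes must be >= ``min_span``.
    Windows masked polymorphic are skipped entirely.  Calls are named
    ``<gene>_NP<k>`` in 5'->3' order within each window and returned sorted
    by (window order, start).
    """
    for s in (wt_nuc, q_nuc, wt_ref, q_ref):
        s.check_layout(layout)
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if mask is None:
        mask = RegionMask.all_analyzable(layout)
    if max_gap is None:
        if layout.step is None:
            raise ValueError("layout has no tiling step; pass max_gap explicitly")
        max_gap = layout.step

    _, nuc_p, nuc_testable = ttest_matrix(
        wt_nuc.values, q_nuc.values, equal_var=equal_var
    )
    _, ref_p, ref_testable = ttest_matrix(
        wt_ref.values, q_ref.values, equal_var=equal_var
    )
    wt_profile = average_profile(wt_nuc)
    q_profile = average_profile(q_nuc)
    delta = q_profile - wt_profile

    with np.errstate(invalid="ignore"):
        qualifies = nuc_testable & ref_testable & (nuc_p <= alpha) & (ref_p > alpha)

    calls: list[NPCall] = []
    for w in layout.windows:
        if not mask.is_analyzable(w.window_id):
            continue
        rows = layout.window_probe_rows(w.window_id)
        k = 0
        run: list[int] = []

        def flush(run):
            nonlocal k
            if not run:
                return
            first, last = layout.probes[run[0]], layout.probes[run[-1]]
            span = last.end - first.start + 1
            if span < min_span:
                return
            direction, mean_delta, tie = classify_direction(delta[run])
            k += 1
            calls.append(
                NPCall(
                    window_id=w.window_id,
                    gene_id=w.gene_id,
                    call_name=f"{w.gene_id}_NP{k}",
                    chrom=w.chrom,
                    start=first.start,
                    end=last.end,
                    direction=direction,
                    probe_ids=[layout.probes[r].probe_id for r in run],
                    nuc_p=nuc_p[run].copy(),
                    ref_p=ref_p[run].copy(),
                    mean_delta=mean_delta,
                    zero_tie=tie,
                )
            )

        for r in rows:
            if not qualifies[r]:
                flush(run)
                run = []
                continue
            if run and layout.probes[r].start - layout.probes[run[-1]].start > max_gap:
                flush(run)
                run = []
            run.append(r)
        flush(run)
    return calls


# ---------------------------------------------------------------------------
# Tabular export / import
# ---------------------------------------------------------------------------

CALL_COLUMNS = [
    "window_id",
    "gene_id",
    "call_name",
    "chrom",
    "start",
    "end",
    "span_bp",
    "direction",
    "n_probes",
    "probe_ids",
    "min_nuc_p",
    "max_ref_p",
    "mean_delta",
]


def calls_to_dataframe(calls: list[NPCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "window_id": c.window_id,
                "gene_id": c.gene_id,
                "call_name": c.call_name,
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "span_bp": c.span_bp,
                "direction": c.direction,
                "n_probes": c.n_probes,
                "probe_ids": ",".join(c.probe_ids),
                "min_nuc_p": float(np.nanmin(c.nuc_p)) if c.nuc_p.size else math.nan,
                "max_ref_p": float(np.nanmax(c.ref_p)) if c.ref_p.size else math.nan,
                "mean_delta": c.mean_delta,
            }
        )
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def write_calls_tsv(calls: list[NPCall], path) -> None:
    calls_to_dataframe(calls).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_calls_bed(calls: list[NPCall], path) -> None:
    """BED export (0-based half-open, per BED convention)."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(f"{c.chrom}\t{c.start - 1}\t{c.end}\t{c.call_name}\t0\t+\n")
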