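"""Independent reference implementations used only to check the package.

Everything here is written from textbook formulas and exhaustive
enumeration, deliberately sharing no code with the implementation under
test.
"""

import math

import numpy as np
from scipy.special import stdtr


def textbook_ttest(a, b):
    """Pooled-variance two-sample t from first principles.

    Returns (t, p) with the same degenerate conventions documented by the
    package: both groups constant and equal -> (0, 1); constant and
    unequal -> (+-inf, 0); fewer than 2 values in either group ->
    (nan, nan).  The p-value comes from the t CDF via ``scipy.special``,
    a different route than ``scipy.stats.ttest_ind``.
    """
    a = [x for x in a if not math.isnan(x)]
    b = [x for x in b if not math.isnan(x)]
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        return (math.nan, math.nan)
    ma = sum(a) / na
    mb = sum(b) / nb
    ssa = sum((x - ma) ** 2 for x in a)
    ssb = sum((x - mb) ** 2 for x in b)
    df = na + nb - 2
    sp2 = (ssa + ssb) / df
    se = math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    if se == 0.0:
        if ma == mb:
            return (0.0, 1.0)
        return (math.copysign(math.inf, ma - mb), 0.0)
    t = (ma - mb) / se
    p = 2.0 * stdtr(df, -abs(t))
    return (t, p)


def enumerate_np_calls(
    probes, wt_nuc, q_nuc, wt_ref, q_ref, alpha=0.05, min_span=140, max_gap=50
):
    """Exhaustive-run oracle for differential-NP calling on one window.

    ``probes`` is a list of (start, end); the four matrices are
    probe x replicate.  Every contiguous probe segment is tested: all its
    probes must satisfy the dual condition (nucleosomal p <= alpha AND
    reference p > alpha, both testable), consecutive starts must be within
    ``max_gap``, and the union span must reach ``min_span``.  Qualifying
    segments strictly contained in a longer qualifying segment are
    discarded, leaving the maximal runs.  Returns [(i, j, direction)] with
    inclusive probe indices, direction from the mean replicate-averaged
    nucleosomal difference (query - wild type; gain iff > 0).
    """
    n = len(probes)
    qualify = []
    for r in range(n):
        _, p_nuc = textbook_ttest(wt_nuc[r], q_nuc[r])
        _, p_ref = textbook_ttest(wt_ref[r], q_ref[r])
        ok = (
            not math.isnan(p_nuc)
            and not math.isnan(p_ref)
            and p_nuc <= alpha
            and p_ref > alpha
        )
        qualify.append(ok)

    def segment_ok(i, j):
        if not all(qualify[i : j + 1]):
            return False
        for r in range(i, j):
            if probes[r + 1][0] - probes[r][0] > max_gap:
                return False
        return True

    candidates = [
        (i, j)
        for i in range(n)
        for j in range(i, n)
        if segment_ok(i, j) and probes[j][1] - probes[i][0] + 1 >= min_span
    ]
    maximal = [
        (i, j)
        for (i, j) in candidates
        if not any(
            (i2 <= i and j2 >= j and (i2, j2) != (i, j)) for (i2, j2) in candidates
        )
    ]
    out = []
    for i, j in sorted(maximal):
        deltas = []
        for r in range(i, j + 1):
            wt = [x for x in wt_nuc[r] if not math.isnan(x)]
            q = [x for x in q_nuc[r] if not math.isnan(x)]
            deltas.append(sum(q) / len(q) - sum(wt) / len(wt))
        mean = sum(deltas) / len(deltas)
        out.append((i, j, "gain" if mean > 0 else "loss"))
    return out


def random_window_instance(rng, n_probes=12, n_reps=3):
    """Random two-genotype instance rich in borderline run patterns."""
    wt_nuc = rng.normal(0.0, 0.3, size=(n_probes, n_reps))
    q_nuc = rng.normal(0.0, 0.3, size=(n_probes, n_reps))
    effect = rng.choice([0.0, 1.5, -1.5], size=n_probes, p=[0.45, 0.275, 0.275])
    q_nuc += effect[:, None]
    wt_ref = rng.normal(0.0, 0.3, size=(n_probes, n_reps))
    q_ref = rng.normal(0.0, 0.3, size=(n_probes, n_reps))
    # occasional gDNA shift to disqualify probes, occasional missing cells
    ref_shift = rng.choice([0.0, 2.0], size=n_probes, p=[0.85, 0.15])
    q_ref += ref_shift[:, None]
    if rng.random() < 0.3:
        r = rng.integers(n_probes)
        q_nuc[r, : n_reps - 1] = np.nan  # leaves 1 replicate -> untestable
    return wt_nuc, q_nuc, wt_ref, q_ref
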