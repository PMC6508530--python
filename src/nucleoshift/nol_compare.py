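"""Stage 3: which genotype tracks the sequence-intrinsic prediction?

The nucleosome occupancy likelihood (NOL) is a per-position score predicted
from primary DNA sequence alone.  If a chromatin protein actively positions
nucleosomes *away* from their sequence-favored locations, its loss-of-
function mutant should relax toward the prediction — its measured profile
should correlate better with NOL than the wild type's does.  For each
called NP region we sample the NOL at the region's probe midpoints and
compare the Pearson correlation of each genotype's averaged nucleosomal
profile against those samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .array_io import NOLTrack, ProbeLayout
from .np_caller import NPCall, arraywide_correlation

WILD_TYPE = "wild_type"
MUTANT = "mutant"
INDETERMINATE = "indeterminate"


@dataclass
class NOLVerdict:
    call_name: str
    r_wt: float
    r_query: float
    more_correlated: str  # wild_type | mutant | indeterminate


def nol_classify(
    call: NPCall,
    wt_profile: np.ndarray,
    q_profile: np.ndarray,
    layout: ProbeLayout,
    nol: NOLTrack,
    flank: int = 0,
    tie_epsilon: float = 1e-9,
) -> NOLVerdict:
    """Classify one NP call by NOL correlation.

    Profiles are per-probe mean vectors in the layout's global order.  With
    ``flank`` > 0 the comparison extends to all window probes whose midpoint
    falls within the call interval widened by ``flank`` bp on each side.
    The verdict is *mutant* iff r_query > r_wt strictly, *wild_type* iff
    r_wt > r_query, and *indeterminate* when either correlation is
    undefined (constant input) or |r_query - r_wt| < ``tie_epsilon``.
    """
    w = layout.window(call.window_id)
    if flank == 0:
        rows = [layout.row_of(pid) for pid in call.probe_ids]
    else:
        lo, hi = call.start - flank, call.end + flank
        rows = [
            r
            for r in layout.window_probe_rows(call.window_id)
            if lo <= layout.probes[r].midpoint <= hi
        ]
    midpoints = np.array([layout.probes[r].midpoint for r in rows])
    nol_samples = nol.values_at(w.chrom, midpoints)

    wt = np.asarray(wt_profile, dtype=float)[rows]
    q = np.asarray(q_profile, dtype=float)[rows]
    r_wt = arraywide_correlation(wt, nol_samples)
    r_q = arraywide_correlation(q, nol_samples)

    if math.isnan(r_wt) or math.isnan(r_q) or abs(r_q - r_wt) < tie_epsilon:
        verdict = INDETERMINATE
    elif r_q > r_wt:
        verdict = MUTANT
    else:
        verdict = WILD_TYPE
    return NOLVerdict(call.call_name, r_wt, r_q, verdict)


def nol_classify_all(
    calls: list[NPCall],
    wt_profile: np.ndarray,
    q_profile: np.ndarray,
    layout: ProbeLayout,
    nol: NOLTrack,
    flank: int = 0,
    tie_epsilon: float = 1e-9,
) -> list[NOLVerdict]:
    return [
        nol_classify(c, wt_profile, q_profile, layout, nol, flank, tie_epsilon)
        for c in calls
    ]
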