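"""Post-ablation outcome classification and correlation statistics.

An ablation run is classified from its post-RFA recording as

* ``sinus``  - no self-activation in the final second of the window;
* ``AT``     - activation persists, driven by a single rotor (time-median
  concurrent rotor count of 1) with periodic activation (cycle-length
  coefficient of variation < 10 %);
* ``pAF``    - anything else.

Success (termination of pAF) means sinus or AT.  Relationships between
per-subdivision lesion outcomes, PS density and fibrosis density are
quantified with Pearson product-moment correlations (two-sided p from the
t distribution, n - 2 d.o.f.); densities are normalized to their maximum
across the eight subdivisions, outcome vectors are binary.  Cells whose
outcome vector is constant (all failures or all successes) have an
undefined correlation, rendered as "-" as in the conventional tabulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .monodomain import Recording, activation_times

__all__ = [
    "OutcomeRecord", "StatsResult", "classify_outcome", "pearson",
    "normalize_densities", "correlation_table",
]


@dataclass
class OutcomeRecord:
    lesion_name: str
    classification: str          # sinus | AT | pAF
    rotor_count_series: np.ndarray
    success: int                 # 1 if sinus or AT

    def __post_init__(self):
        assert self.classification in ("sinus", "AT", "pAF")
        self.success = int(self.classification in ("sinus", "AT"))


@dataclass
class StatsResult:
    r: float
    p: float
    n: int
    defined: bool = True

    def __str__(self):
        return f"r={self.r:.2f}, p={self.p:.2f}" if self.defined else "-"


def classify_outcome(post_recording: Recording, trajectories,
                     lesion_name: str = "", rotor_min_duration_ms: float = 120.0,
                     quiet_tail_ms: float = 1000.0,
                     cl_cv_threshold: float = 0.10) -> OutcomeRecord:
    """Classify the rhythm at the end of the post-RFA analysis window."""
    t0, t1 = post_recording.t[0], post_recording.t[-1]
    if t1 - t0 < quiet_tail_ms:
        raise ValueError("analysis window shorter than the quiet-tail test")
    amap = activation_times(post_recording)
    tail = amap.events_t >= t1 - quiet_tail_ms

    # concurrent rotor count per frame over the window tail
    rotors = [tr for tr in trajectories
              if tr.duration > rotor_min_duration_ms]
    times = post_recording.t
    series = np.zeros(len(times), dtype=int)
    lo = np.searchsorted(times, t1 - quiet_tail_ms)
    for tr in rotors:
        i0 = np.searchsorted(times, tr.birth)
        i1 = np.searchsorted(times, tr.death, side="right")
        series[i0:i1] += 1

    if not tail.any():
        cls = "sinus"
    else:
        med_rotors = int(np.median(series[lo:]))
        # periodicity: pooled per-node cycle lengths over the tail
        ev_nodes = amap.events_node[tail]
        ev_t = amap.events_t[tail]
        order = np.lexsort((ev_t, ev_nodes))
        nn, tt = ev_nodes[order], ev_t[order]
        dt = np.diff(tt)[np.diff(nn) == 0]
        cv = (np.std(dt) / np.mean(dt)) if len(dt) >= 4 else np.inf
        cls = "AT" if (med_rotors == 1 and cv < cl_cv_threshold) else "pAF"
    return OutcomeRecord(lesion_name, cls, series, 0)


def pearson(x, y) -> StatsResult:
    """Pearson product-moment correlation with two-sided p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return StatsResult(np.nan, np.nan, len(x), defined=False)
    r, p = _sps.pearsonr(x, y)
    return StatsResult(float(r), float(p), len(x))


def normalize_densities(values) -> np.ndarray:
    """Scale a per-subdivision vector by its maximum (0-1); an all-zero
    vector is returned unchanged.  Binary outcome vectors pass through
    unchanged by construction (max = 1)."""
    v = np.asarray(values, dtype=float)
    mx = v.max()
    return v / mx if mx > 0 else v


def correlation_table(outcomes: dict, ps_density, fib_density) -> pd.DataFrame:
    """Correlations of binary lesion outcomes against PS and fibrosis
    density per shape x size.

    ``outcomes`` maps (shape, size_cm) -> 8-vector of 0/1 per
    subdivision.  Undefined correlations (constant outcome vector) are
    rendered "-".
    """
    psd = normalize_densities(ps_density)
    fbd = normalize_densities(fib_density)
    rows = []
    for (shape, size), vec in outcomes.items():
        vec = np.asarray(vec, float)
        if set(np.unique(vec)) - {0.0, 1.0}:
            raise ValueError("outcome vectors must be binary")
        rf = pearson(fbd, vec)
        rp = pearson(psd, vec)
        rows.append({
            "shape": shape, "size_cm": size,
            "r_fibrosis": f"{rf.r:.2f}" if rf.defined else "-",
            "p_fibrosis": f"{rf.p:.2f}" if rf.defined else "-",
            "r_ps": f"{rp.r:.2f}" if rp.defined else "-",
            "p_ps": f"{rp.p:.2f}" if rp.defined else "-",
        })
    return pd.DataFrame(rows)
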