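"""Anatomical-consistency enforcement and boundary extraction.

Skin strata are strictly ordered with depth: epidermis above the
dermal-epidermal junction (DEJ) above the dermis, and the sequence of
per-slice labels down a stack must therefore be monotone non-decreasing in
the ordinal coding epidermis(0) < DEJ(1) < dermis(2).  Raw per-slice
predictions can violate this.  The two-step heuristic applied here first
removes isolated outliers with a 3-slice median filter and then enforces
monotonicity with a causal max filter (an inclusive prefix maximum), after
which boundary depths follow directly from the first label transitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stack_io import StrataLabelSequence

__all__ = [
    "BoundaryEstimate", "median_filter3", "causal_max",
    "enforce_consistency", "extract_boundaries",
]


@dataclass
class BoundaryEstimate:
    """Depths (um) of the epidermis-DEJ and DEJ-dermis boundaries.

    A boundary is ``None`` when the deeper stratum never appears in the
    label sequence; such values are excluded pairwise from error metrics.
    """

    epi_dej_um: float | None
    dej_derm_um: float | None
    stack_id: str = ""

    def __post_init__(self):
        if (self.epi_dej_um is not None and self.dej_derm_um is not None
                and self.epi_dej_um > self.dej_derm_um):
            raise ValueError("epidermis-DEJ boundary cannot lie below "
                             "the DEJ-dermis boundary")


def _as_labels(labels) -> np.ndarray:
    arr = np.asarray(getattr(labels, "labels", labels), dtype=np.int64)
    if arr.ndim != 1 or len(arr) < 1:
        raise ValueError("need a non-empty 1-D label sequence")
    return arr


def _wrap(labels, values: np.ndarray):
    if isinstance(labels, StrataLabelSequence):
        return StrataLabelSequence(values, stack_id=labels.stack_id)
    return values


def median_filter3(labels):
    """3-slice running median over the ordinal labels.

    Edge handling is asymmetric, because the causal max filter that follows
    propagates labels downward only: an outlier on the FIRST slice would
    corrupt every deeper prediction once the max filter locks it in, so the
    shallow edge uses the nearest full window (slices 0..2) and lets the
    neighbours vote it out.  A trailing outlier poisons nothing, so the
    deep edge replicates the terminal label and single-slice tails survive.
    Constant sequences are fixed points and length is preserved.
    """
    arr = _as_labels(labels)
    n = len(arr)
    if n < 3:
        return _wrap(labels, arr.copy())
    centers = np.clip(np.arange(n), 1, n - 1)
    upper = np.minimum(centers + 1, n - 1)
    win = np.stack([arr[centers - 1], arr[centers], arr[upper]])
    return _wrap(labels, np.median(win, axis=0).astype(np.int64))


def causal_max(labels):
    """Inclusive prefix maximum: output[n] = max(input[0..n]).

    The output is monotone non-decreasing by construction and the filter is
    idempotent; an already monotone sequence passes through unchanged.
    """
    arr = _as_labels(labels)
    return _wrap(labels, np.maximum.accumulate(arr))


def enforce_consistency(labels):
    """Median filter, causal max, then DEJ bridging: zero illegal transitions.

    The median/max composition yields a monotone sequence, which rules out
    every depth-order violation except one: a direct epidermis->dermis jump
    between adjacent slices, which skips the junction zone that must lie
    between them.  Where such a jump survives, the first dermis slice is
    relabelled DEJ (the junction is placed at the transition).  The result
    is monotone, contains none of the four anatomically impossible
    transitions, and the operation is idempotent.
    """
    arr = causal_max(median_filter3(labels))
    out = np.asarray(getattr(arr, "labels", arr))
    jump = np.nonzero((out[:-1] == 0) & (out[1:] == 2))[0]
    if len(jump):
        out = out.copy()
        out[jump[0] + 1] = 1     # monotone output has at most one 0->2 jump
    return _wrap(labels, out)


def extract_boundaries(labels, axial_step_um: float,
                       depth_origin_um: float = 0.0,
                       stack_id: str | None = None) -> BoundaryEstimate:
    """Boundary depths from a consistency-enforced label sequence.

    The epidermis-DEJ boundary is the depth of the first slice labelled DEJ
    or deeper; the DEJ-dermis boundary that of the first dermis slice.  A
    missing stratum yields a ``None`` boundary.  Slice ``i`` sits at depth
    ``depth_origin_um + i * axial_step_um``.
    """
    arr = _as_labels(labels)
    if axial_step_um <= 0:
        raise ValueError("axial_step_um must be positive")
    if (np.diff(arr) < 0).any():
        raise ValueError("labels are not monotone: enforce consistency first")

    def first_depth(cond: np.ndarray):
        hits = np.nonzero(cond)[0]
        if not len(hits):
            return None
        return float(depth_origin_um + hits[0] * axial_step_um)

    sid = stack_id if stack_id is not None else getattr(labels, "stack_id", "")
    return BoundaryEstimate(epi_dej_um=first_depth(arr >= 1),
                            dej_derm_um=first_depth(arr == 2),
                            stack_id=sid)
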