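"""Evaluation metrics: slice classification, consistency, boundary error.

Three surfaces mirror how strata classifiers are judged:

* per-slice accuracy with one-vs-rest sensitivity and specificity per class;
* counts of the four anatomically impossible adjacent-slice transitions
  (epidermis->dermis, DEJ->epidermis, dermis->epidermis, dermis->DEJ),
  evaluated on raw model output where they diagnose how well a model
  internalized the depth ordering;
* mean absolute error (um) of the two boundary depths extracted from
  post-processed labels against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix

from .postprocessing import (BoundaryEstimate, enforce_consistency,
                             extract_boundaries)
from .stack_io import StrataLabelSequence

__all__ = [
    "ConsistencyReport", "ClassificationReport", "count_inconsistencies",
    "classification_report", "boundary_mae", "evaluate_run",
]

#: Illegal (shallower, deeper) adjacent label pairs, in report order.
ILLEGAL_PAIRS = {
    (0, 2): "epi_to_derm",
    (1, 0): "dej_to_epi",
    (2, 0): "derm_to_epi",
    (2, 1): "derm_to_dej",
}


@dataclass
class ConsistencyReport:
    epi_to_derm: int = 0
    dej_to_epi: int = 0
    derm_to_epi: int = 0
    derm_to_dej: int = 0

    @property
    def total(self) -> int:
        return (self.epi_to_derm + self.dej_to_epi + self.derm_to_epi
                + self.derm_to_dej)

    def __add__(self, other: "ConsistencyReport") -> "ConsistencyReport":
        return ConsistencyReport(
            self.epi_to_derm + other.epi_to_derm,
            self.dej_to_epi + other.dej_to_epi,
            self.derm_to_epi + other.derm_to_epi,
            self.derm_to_dej + other.derm_to_dej)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["total"] = self.total
        return d


@dataclass
class ClassificationReport:
    accuracy: float
    sensitivity: tuple            # per class, NaN where the class is absent
    specificity: tuple
    confusion: np.ndarray         # rows = truth, cols = prediction

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy,
                "sensitivity": list(self.sensitivity),
                "specificity": list(self.specificity),
                "confusion": self.confusion.tolist()}


def count_inconsistencies(labels) -> ConsistencyReport:
    """Count illegal adjacent-slice transitions, one per offending pair."""
    arr = np.asarray(getattr(labels, "labels", labels), dtype=np.int64)
    if arr.ndim != 1 or len(arr) < 1:
        raise ValueError("need a non-empty 1-D label sequence")
    rep = ConsistencyReport()
    for a, b in zip(arr[:-1], arr[1:]):
        name = ILLEGAL_PAIRS.get((int(a), int(b)))
        if name is not None:
            setattr(rep, name, getattr(rep, name) + 1)
    return rep


def _flatten(seqs) -> np.ndarray:
    if isinstance(seqs, (StrataLabelSequence, np.ndarray)):
        seqs = [seqs]
    elif isinstance(seqs, (list, tuple)) and seqs and np.isscalar(seqs[0]):
        seqs = [seqs]  # a bare list of integer labels is one sequence
    return np.concatenate([
        np.asarray(getattr(s, "labels", s), dtype=np.int64) for s in seqs])


def classification_report(truth, pred) -> ClassificationReport:
    """Accuracy plus one-vs-rest sensitivity/specificity for the 3 classes.

    ``truth``/``pred`` may be single sequences or lists of sequences; lists
    are concatenated slice-wise.  A class absent from the truth gets NaN
    sensitivity (0/0), to be excluded from macro summaries.
    """
    t, p = _flatten(truth), _flatten(pred)
    if len(t) != len(p):
        raise ValueError("truth and prediction lengths differ")
    cm = confusion_matrix(t, p, labels=[0, 1, 2])
    sens, spec = [], []
    for c in range(3):
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = cm.sum() - tp - fn - fp
        sens.append(tp / (tp + fn) if (tp + fn) else float("nan"))
        spec.append(tn / (tn + fp) if (tn + fp) else float("nan"))
    return ClassificationReport(accuracy=float(np.trace(cm) / cm.sum()),
                                sensitivity=tuple(sens),
                                specificity=tuple(spec), confusion=cm)


def boundary_mae(estimates, truths):
    """Mean absolute boundary error in um, separately per boundary.

    Estimates and truths are matched by ``stack_id``.  Pairs where either
    side lacks a boundary are excluded and counted.  Returns a dict with
    the two MAEs, exclusion counts and per-stack signed errors (estimate
    minus truth, for histogramming).
    """
    est_by_id = {e.stack_id: e for e in estimates}
    tru_by_id = {t.stack_id: t for t in truths}
    common = [sid for sid in est_by_id if sid in tru_by_id]
    if not common:
        raise ValueError("no overlapping stack_ids between estimates and truth")
    out = {}
    for key in ("epi_dej_um", "dej_derm_um"):
        signed, excluded = {}, 0
        for sid in common:
            e, t = getattr(est_by_id[sid], key), getattr(tru_by_id[sid], key)
            if e is None or t is None:
                excluded += 1
                continue
            signed[sid] = float(e - t)
        name = key.replace("_um", "")
        vals = np.array(list(signed.values()))
        out[f"mae_{name}_um"] = float(np.abs(vals).mean()) if len(vals) else float("nan")
        out[f"excluded_{name}"] = excluded
        out[f"signed_errors_{name}"] = signed
    return out


def evaluate_run(predictions: pd.DataFrame, truth_labels: dict,
                 manifest: pd.DataFrame) -> dict:
    """Composite report for one prediction table against ground truth.

    ``truth_labels`` maps stack_id -> StrataLabelSequence; ``manifest``
    carries per-stack geometry and true boundary depths (columns stack_id,
    axial_step_um, depth_origin_um, epi_dej_um, dej_derm_um).  Classification
    is scored on raw argmax labels, consistency on both raw and
    post-processed labels, boundary MAE on post-processed labels.  Stacks
    missing from the predictions are listed and skipped.
    """
    if len(predictions) == 0:
        raise ValueError("empty prediction table")
    geo = manifest.set_index("stack_id")
    missing = [sid for sid in truth_labels
               if sid not in set(predictions["stack_id"])]
    raw_cons = ConsistencyReport()
    post_cons = ConsistencyReport()
    truth_seqs, raw_seqs = [], []
    est_bounds, true_bounds = [], []
    for sid, grp in predictions.groupby("stack_id", sort=True):
        if sid not in truth_labels:
            continue
        grp = grp.sort_values("slice_index")
        raw = grp["argmax_label"].to_numpy(dtype=np.int64)
        truth = truth_labels[sid].labels[:len(raw)]
        truth_seqs.append(truth)
        raw_seqs.append(raw)
        raw_cons = raw_cons + count_inconsistencies(raw)
        post = enforce_consistency(raw)
        post_cons = post_cons + count_inconsistencies(post)
        row = geo.loc[sid]
        origin = float(row.get("depth_origin_um", 0.0))
        est_bounds.append(extract_boundaries(
            post, float(row["axial_step_um"]), origin, stack_id=sid))
        true_bounds.append(BoundaryEstimate(
            epi_dej_um=float(row["epi_dej_um"]),
            dej_derm_um=float(row["dej_derm_um"]), stack_id=sid))
    cls = classification_report(truth_seqs, raw_seqs)
    mae = boundary_mae(est_bounds, true_bounds)
    return {
        "classification": cls.as_dict(),
        "consistency_raw": raw_cons.as_dict(),
        "consistency_postprocessed": post_cons.as_dict(),
        "boundary_mae": {k: v for k, v in mae.items()
                         if not k.startswith("signed_errors")},
        "signed_errors": {k: v for k, v in mae.items()
                          if k.startswith("signed_errors")},
        "missing_stacks": sorted(missing),
    }


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
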