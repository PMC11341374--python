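"""Agreement between automatic and reference (manual) artifact grids.

Two entry points: :func:`confusion_from_grids` counts channel-segment
elements of two aligned grids, and :func:`metrics_from_summary`
reconstructs the full metric set from published summary values (element
count, both prevalences, and sensitivity), keeping real-valued counts so
rounding of the inputs propagates transparently.
"""

from __future__ import annotations

import numpy as np

from .grids import ArtifactGrid
from .model_io import ConfusionMetrics


def confusion_from_grids(test_grid: ArtifactGrid,
                         ref_grid: ArtifactGrid) -> ConfusionMetrics:
    """Element-wise confusion counts of a test grid against a reference.

    Cohen's kappa uses chance agreement
    ``pe = prev_test*prev_ref + (1-prev_test)*(1-prev_ref)``. Ratios with
    zero denominators are NaN.
    """
    t, r = test_grid.values, ref_grid.values
    if t.shape != r.shape:
        raise ValueError(f"grid shapes differ: {t.shape} vs {r.shape}")
    tp = int(np.sum(t & r))
    fp = int(np.sum(t & ~r))
    fn = int(np.sum(~t & r))
    tn = int(np.sum(~t & ~r))
    return ConfusionMetrics.from_counts(tp, fp, fn, tn)


def metrics_from_summary(n_elements: float, prevalence_ref: float,
                         prevalence_test: float,
                         sensitivity: float) -> ConfusionMetrics:
    """Reconstruct a full metric set from published summary values.

    With N elements, reference prevalence p_r, test prevalence p_t and
    sensitivity s: P = p_r*N, TP = s*P, FP = p_t*N - TP, FN = P - TP,
    TN = N - P - FP. Counts stay real-valued (no integer rounding).
    """
    for name, v in (("prevalence_ref", prevalence_ref),
                    ("prevalence_test", prevalence_test),
                    ("sensitivity", sensitivity)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if n_elements <= 0:
        raise ValueError("n_elements must be positive")
    p = prevalence_ref * n_elements
    tp = sensitivity * p
    fp = prevalence_test * n_elements - tp
    if fp < -1e-9:
        raise ValueError("inconsistent summary: test prevalence implies "
                         "negative false positives")
    fp = max(fp, 0.0)
    fn = p - tp
    tn = n_elements - p - fp
    return ConfusionMetrics.from_counts(tp, fp, fn, tn)


def injection_recovery(detected, ground_truth, target_types=None):
    """Event-level sensitivity and precision against injected ground truth.

    A ground-truth event is *recovered* when the detector's events on the
    same channel cover at least 50% of the injected span. A detected event
    is a *true detection* when it overlaps any ground-truth event on its
    channel (any artifact class): detectors legitimately co-detect other
    classes' injections, which is cross-talk rather than false detection.

    Parameters
    ----------
    detected : EventTable from one detector.
    ground_truth : EventTable of injected artifacts.
    target_types : artifact classes this detector targets (None = all);
        only these ground-truth events enter the sensitivity denominator.

    Returns
    -------
    dict with ``sensitivity``, ``precision``, ``n_truth``, ``n_detected``.
    """
    gt = ground_truth.df
    if target_types is not None:
        gt_target = gt[gt["event_type"].isin(list(target_types))]
    else:
        gt_target = gt
    det = detected.df

    def overlap(a0, a1, b0, b1):
        return max(0.0, min(a1, b1) - max(a0, b0))

    recovered = 0
    for row in gt_target.itertuples(index=False):
        ev = det[det["channel"] == row.channel]
        cov = sum(overlap(row.start_s, row.end_s, r.start_s, r.end_s)
                  for r in ev.itertuples(index=False))
        if cov >= 0.5 * (row.end_s - row.start_s):
            recovered += 1

    true_det = 0
    for r in det.itertuples(index=False):
        g = gt[gt["channel"] == r.channel]
        if any(overlap(r.start_s, r.end_s, row.start_s, row.end_s) > 0
               for row in g.itertuples(index=False)):
            true_det += 1

    n_t, n_d = len(gt_target), len(det)
    return {
        "sensitivity": recovered / n_t if n_t else float("nan"),
        "precision": true_det / n_d if n_d else float("nan"),
        "n_truth": n_t,
        "n_detected": n_d,
    }
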