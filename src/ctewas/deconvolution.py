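"""Reference-based estimation of cell proportions in bulk samples.

A reference panel holds mean beta profiles of the sorted cell types at
the most cell-type-discriminative probes (top-k by t-test p, default
k = 600).  For each bulk sample the cell-type weights solve the
constrained least-squares projection

    min_w || b - R w ||^2   subject to   w >= 0,  sum(w) <= 1,

so the neuronal proportion is the ``neuron`` weight and any remainder
1 - sum(w) is unexplained signal.  The module also implements the
reference-age experiment: when markers carry cell-type-specific age
slopes, panels built from young versus old reference donors yield
systematically different proportion estimates for the same bulk samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .diffmeth import celltype_ttest
from .errors import ContractError, ValidationError
from .synthetic import SyntheticDesign, generate_bulk_cohort, generate_sorted_cohort

log = logging.getLogger(__name__)


@dataclass
class ReferencePanel:
    """Marker probes with mean reference beta per cell type.

    ``reference``: markers x cell types DataFrame (columns e.g. neuron,
    glia); ``metadata``: provenance of the reference samples (n per
    fraction, age range).
    """

    reference: pd.DataFrame
    metadata: dict

    @property
    def markers(self) -> pd.Index:
        return self.reference.index

    @property
    def cell_types(self) -> list:
        return list(self.reference.columns)


def select_reference_markers(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    k: int = 600,
    controls_only: bool = True,
    balanced: bool = False,
) -> ReferencePanel:
    """Top-k probes from the neuron-vs-glia t test, with reference means.

    Markers are ranked by ascending p (ties by probe id).  ``balanced``
    instead takes k/2 probes hypermethylated in neurons and k/2
    hypomethylated.
    """
    tests = celltype_ttest(beta, sheet, controls_only=controls_only)
    if k > len(tests):
        raise ContractError(f"k={k} exceeds {len(tests)} tested probes")
    ranked = tests.sort_values("rank")
    if balanced:
        half = k // 2
        hyper = ranked.index[ranked["effect"] > 0][:half]
        hypo = ranked.index[ranked["effect"] < 0][: k - half]
        markers = hyper.append(hypo)
    else:
        markers = ranked.index[:k]
    sub = sheet.loc[sheet.index.intersection(beta.columns)]
    if controls_only:
        sub = sub[sub["diagnosis"] == "control"]
    ref = {}
    meta = {}
    for fraction in ("neuron", "glia"):
        ids = sub.index[sub["cell_fraction"] == fraction]
        ref[fraction] = beta.loc[markers, ids].mean(axis=1)
        ages = sub.loc[ids, "age"]
        meta[fraction] = {"n": int(len(ids)), "age_min": float(ages.min()), "age_max": float(ages.max())}
    return ReferencePanel(reference=pd.DataFrame(ref), metadata=meta)


def _project_sample(R: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, bool]:
    """Solve min ||b - R w||^2 s.t. w >= 0, sum(w) <= 1 (SLSQP, w0 = 0)."""
    k = R.shape[1]
    RtR, Rtb = R.T @ R, R.T @ b

    def fun(w):
        return 0.5 * w @ RtR @ w - Rtb @ w

    def jac(w):
        return RtR @ w - Rtb

    res = optimize.minimize(
        fun,
        np.zeros(k),
        jac=jac,
        method="SLSQP",
        bounds=[(0.0, None)] * k,
        constraints=[{"type": "ineq", "fun": lambda w: 1.0 - w.sum(), "jac": lambda w: -np.ones(k)}],
        options={"ftol": 1e-14, "maxiter": 500},
    )
    w = np.clip(res.x, 0.0, None)
    return w, bool(res.success)


def estimate_proportions(bulk: pd.DataFrame, panel: ReferencePanel) -> pd.DataFrame:
    """Constrained projection of each bulk sample onto the panel.

    Markers missing from the bulk matrix are dropped (logged); samples
    where the solver fails are flagged in the ``converged`` column.
    Returns per sample: one weight column per cell type, residual_norm,
    converged.  Estimates do not depend on marker order.
    """
    markers = panel.markers.intersection(bulk.index)
    if len(markers) == 0:
        raise ValidationError("no panel markers present in the bulk matrix")
    if len(markers) < len(panel.markers):
        log.info("%d of %d markers missing from bulk matrix; dropped",
                 len(panel.markers) - len(markers), len(panel.markers))
    # canonical marker order: estimates are order-invariant, logs stable
    markers = markers.sort_values()
    R = panel.reference.loc[markers].to_numpy(dtype=float)
    rows = []
    for sample in bulk.columns:
        b = bulk.loc[markers, sample].to_numpy(dtype=float)
        ok = ~np.isnan(b)
        w, converged = _project_sample(R[ok], b[ok])
        resid = float(np.linalg.norm(b[ok] - R[ok] @ w))
        rows.append([*w, resid, converged])
    cols = [f"w_{ct}" for ct in panel.cell_types] + ["residual_norm", "converged"]
    return pd.DataFrame(rows, index=pd.Index(bulk.columns, name="sample_id"), columns=cols)


def reference_age_bias_experiment(
    design: SyntheticDesign,
    young: tuple = (30.0, 45.0),
    old: tuple = (75.0, 95.0),
    n_bulk: int = 50,
    n_ref: int = 25,
    k_markers: int = 600,
    seed: int | None = None,
) -> dict:
    """Estimate one bulk cohort with a young-donor and an old-donor panel.

    Both panels select their own top-k markers from sorted reference
    cohorts drawn in the respective age windows (all diagnoses, since the
    old window is depleted of low-Braak donors).  Returns the per-sample
    paired difference of neuronal-proportion estimates (young - old
    reference), its mean, and the two estimate tables.
    """
    for name, (lo, hi) in (("young", young), ("old", old)):
        if hi <= lo:
            raise ContractError(f"empty {name} age window")
    base = design.seed if seed is None else seed
    panels = {}
    for offset, (name, window) in enumerate([("young", young), ("old", old)]):
        d = replace(design, seed=int(base + 11 + offset))
        beta, sheet, _ = generate_sorted_cohort(d, n_ref, age_range=window, cohort=f"ref_{name}")
        panels[name] = select_reference_markers(
            beta, sheet, k=min(k_markers, len(beta)), controls_only=False
        )
    bulk, bulk_sheet = generate_bulk_cohort(replace(design, seed=int(base + 13)), n_bulk)
    est = {name: estimate_proportions(bulk, panel) for name, panel in panels.items()}
    diff = est["young"]["w_neuron"] - est["old"]["w_neuron"]
    return {
        "paired_diff": diff,
        "mean_diff": float(diff.mean()),
        "estimates": est,
        "true_neuron_prop": bulk_sheet["true_neuron_prop"],
        "panels": panels,
    }
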