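"""Reference-based decomposition and angle-driven component selection.

Every test sample ``x`` is paired with a class reference profile (the
feature-wise mean of the control samples, or of the disease samples) to
form a two-row mixture

    [x_ref; x] = A S

which is decomposed by the two-stage sparse component analysis pipeline:
SCP selection -> clustering of SCP directions into the mixing matrix ->
batch l1 recovery of the M source components. Selection of which recovered
component is disease-specific and which control-specific uses the mixing
angles only -- never the labels:

* control reference: the maximal-angle component is disease-specific, the
  minimal-angle one control-specific;
* disease reference: the logic is reversed.

The remaining M - 2 components are neutral (not differentially expressed);
postulating them lets slowly-varying features be absorbed away from the
discriminative components, sample by sample. Running both reference pairings
over all N samples yields four labelled N x K feature-vector sets
(controlref_disease, controlref_control, diseaseref_control,
diseaseref_disease) that downstream classifiers train on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datasets import ExpressionDataset
from .errors import DimensionError, ScamixError
from .mixing import MixingEstimate, cluster_mixing, orient_scp_vectors
from .scp import analytic_mixture, select_scps
from .solver import SolverConfig, SourceEstimate, ist_solve

__all__ = [
    "ReferencePairLMM", "SelectedComponents", "ComponentFeatureSets",
    "SET_NAMES", "build_reference", "decompose_sample", "select_components",
    "extract_feature_sets",
]

log = logging.getLogger(__name__)

#: canonical order of the four labelled component sets
SET_NAMES = ("controlref_disease", "controlref_control",
             "diseaseref_control", "diseaseref_disease")


@dataclass
class ReferencePairLMM:
    """Two-row mixture: row 0 = reference profile, row 1 = test sample."""

    rows: np.ndarray
    reference_role: str          # "control" | "disease"
    test_sample_id: str
    test_label: int

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.ndim != 2 or self.rows.shape[0] != 2:
            raise DimensionError(f"LMM rows must be 2 x K, got {self.rows.shape}")
        if self.reference_role not in ("control", "disease"):
            raise ValueError(f"unknown reference role {self.reference_role!r}")


@dataclass
class SelectedComponents:
    """Disease/control/neutral split of one sample's recovered components."""

    disease_component: np.ndarray
    control_component: np.ndarray
    neutral_components: np.ndarray       # (M-2) x K, empty for M = 2
    disease_angle: float
    control_angle: float
    provenance: dict = field(default_factory=dict)


@dataclass
class ComponentFeatureSets:
    """The four labelled N x K component sets plus extraction parameters."""

    sets: dict[str, np.ndarray]
    labels: np.ndarray
    sample_ids: list[str]
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, mat in self.sets.items():
            if mat.shape[0] != len(self.labels):
                raise DimensionError(
                    f"set {name!r} has {mat.shape[0]} rows for "
                    f"{len(self.labels)} labels")


def build_reference(dataset: ExpressionDataset, class_label: int,
                    exclude_ids=None) -> np.ndarray:
    """Feature-wise mean profile of one class, optionally excluding samples."""
    exclude = set(exclude_ids or ())
    mask = (dataset.labels == class_label) & \
        np.array([sid not in exclude for sid in dataset.sample_ids])
    if not mask.any():
        role = "disease" if class_label == 1 else "control"
        raise ScamixError(f"no {role} samples left to build a reference from")
    return dataset.values[mask].mean(axis=0)


def decompose_sample(lmm: ReferencePairLMM, M: int, delta_theta: float,
                     solver: SolverConfig,
                     strict_diversity: bool = False
                     ) -> tuple[MixingEstimate, SourceEstimate]:
    """SCP selection -> clustering -> batch l1 solve on one two-row mixture.

    By default a sample whose SCPs span fewer than M distinct directions is
    decomposed with duplicated mixing columns rather than rejected (set
    ``strict_diversity`` to make it an error instead).
    """
    try:
        analytic = analytic_mixture(lmm.rows)
        scps = select_scps(analytic, delta_theta)
        vectors = orient_scp_vectors(lmm.rows, scps)
        mix = cluster_mixing(vectors, M, strict_diversity=strict_diversity)
        src = ist_solve(mix.A, lmm.rows, solver)
    except ScamixError as exc:
        raise type(exc)(
            f"sample {lmm.test_sample_id!r} ({lmm.reference_role} reference, "
            f"M={M}, delta_theta={delta_theta}): {exc}") from exc
    return mix, src


def select_components(mixing: MixingEstimate, sources: SourceEstimate,
                      reference_role: str, provenance: dict | None = None
                      ) -> SelectedComponents:
    """Assign disease/control/neutral roles from the mixing angles alone.

    Ties at the extremal angle resolve to the lowest column index, with a
    warning. The selected components always satisfy: control reference ->
    disease angle > control angle; disease reference -> the reverse.
    """
    angles = mixing.angles
    if len(angles) < 2:
        raise DimensionError("need at least 2 components to select from")
    hi = int(np.argmax(angles))  # first occurrence wins on ties
    lo = int(np.argmin(angles))
    if np.count_nonzero(angles == angles[hi]) > 1 or \
            np.count_nonzero(angles == angles[lo]) > 1:
        log.warning("angle tie at the extremum; lowest column index wins")
    if reference_role == "control":
        d_idx, c_idx = hi, lo
    elif reference_role == "disease":
        d_idx, c_idx = lo, hi
    else:
        raise ValueError(f"unknown reference role {reference_role!r}")
    neutral = [m for m in range(len(angles)) if m not in (d_idx, c_idx)]
    return SelectedComponents(
        disease_component=sources.S[d_idx],
        control_component=sources.S[c_idx],
        neutral_components=sources.S[neutral],
        disease_angle=float(angles[d_idx]),
        control_angle=float(angles[c_idx]),
        provenance={"reference_role": reference_role, **(provenance or {})},
    )


def extract_feature_sets(dataset: ExpressionDataset, M: int, delta_theta: float,
                         solver: SolverConfig, reference_policy: str = "train_only",
                         train_ids=None) -> ComponentFeatureSets:
    """Decompose every sample against both references; collect the four sets.

    With ``reference_policy="train_only"`` the class references are averaged
    over ``train_ids`` exclusively (no test-fold leakage); ``"all"``
    averages over every sample. Any per-sample failure aborts with the
    offending sample id -- samples are never silently skipped.
    """
    if reference_policy not in ("train_only", "all"):
        raise ValueError(f"unknown reference policy {reference_policy!r}")
    if reference_policy == "train_only" and train_ids is not None:
        include = set(train_ids)
        exclude = [sid for sid in dataset.sample_ids if sid not in include]
    else:
        exclude = None
    sub_labels = [dataset.labels[i] for i, sid in enumerate(dataset.sample_ids)
                  if exclude is None or sid not in exclude]
    if 1 not in sub_labels or -1 not in sub_labels:
        raise ScamixError("both classes are required to build references")
    ref_control = build_reference(dataset, -1, exclude_ids=exclude)
    ref_disease = build_reference(dataset, 1, exclude_ids=exclude)

    n, k = dataset.values.shape
    out = {name: np.empty((n, k)) for name in SET_NAMES}
    prov = {"M": M, "delta_theta": delta_theta,
            "lambda_multiplier": solver.lambda_multiplier}
    for i in range(n):
        x = dataset.values[i]
        sid = dataset.sample_ids[i]
        for role, ref in (("control", ref_control), ("disease", ref_disease)):
            lmm = ReferencePairLMM(rows=np.vstack([ref, x]), reference_role=role,
                                   test_sample_id=sid,
                                   test_label=int(dataset.labels[i]))
            mix, src = decompose_sample(lmm, M, delta_theta, solver)
            sel = select_components(mix, src, role, provenance=prov)
            out[f"{role}ref_disease"][i] = sel.disease_component
            out[f"{role}ref_control"][i] = sel.control_component
    return ComponentFeatureSets(sets=out, labels=dataset.labels.copy(),
                                sample_ids=list(dataset.sample_ids),
                                params={**prov, "reference_policy": reference_policy})
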