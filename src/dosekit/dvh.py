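"""Cumulative DVHs, the 14-index evaluation set, and delta-error scoring.

The evaluation protocol compares predicted against ground-truth dose
through 14 dose-volume-histogram indices — D95, D90, D50, Dmax, Dmean of
the PTV; V30, Dmax, Dmean of bladder and rectum; Dmax of spinal cord and
of each femoral head — and the per-index error

    delta_i = |D_i(ground truth) - D_i(predicted)| / prescription x 100%

expressed as a percentage of the prescription dose.  Model selection uses
the "% of best prediction": the fraction of the 14 indices on which a
model attains the smallest mean error across test cases (ties credit all
tied models).

Conventions: DVHs are exact sort-based curves (no dose binning); Dp is an
order statistic, the largest voxel dose d such that at least p% of the
structure receives >= d; Vd is the percentage of structure volume
receiving >= d Gy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "INDEX_ORDER",
    "DVH",
    "DVHIndexSet",
    "ErrorReport",
    "cumulative_dvh",
    "dose_at_volume",
    "volume_at_dose",
    "index_set",
    "delta_errors",
    "best_model_fraction",
]

#: the 14 evaluation indices, in fixed (structure, index) order
INDEX_ORDER: tuple[tuple[str, str], ...] = (
    ("ptv", "D95"),
    ("ptv", "D90"),
    ("ptv", "D50"),
    ("ptv", "Dmax"),
    ("ptv", "Dmean"),
    ("bladder", "V30"),
    ("bladder", "Dmax"),
    ("bladder", "Dmean"),
    ("rectum", "V30"),
    ("rectum", "Dmax"),
    ("rectum", "Dmean"),
    ("spinal_cord", "Dmax"),
    ("femoral_head_l", "Dmax"),
    ("femoral_head_r", "Dmax"),
)

#: structures entering the index set
INDEX_STRUCTURES = tuple(dict.fromkeys(s for s, _ in INDEX_ORDER))


@dataclass(frozen=True)
class DVH:
    """Exact cumulative DVH of one structure.

    ``doses`` are the masked voxel doses sorted ascending; ``volume(d)``
    is the fraction of the structure receiving at least ``d``.
    """

    doses: np.ndarray  # sorted ascending, one entry per masked voxel

    @property
    def n(self) -> int:
        return len(self.doses)

    def volume(self, d) -> np.ndarray:
        """Fractional volume receiving >= d (vectorized in d)."""
        idx = np.searchsorted(self.doses, np.asarray(d, dtype=float), side="left")
        return (self.n - idx) / self.n

    @property
    def curve(self) -> tuple[np.ndarray, np.ndarray]:
        """(sorted dose values, fractional volume >= dose) point pairs."""
        return self.doses, self.volume(self.doses)


def cumulative_dvh(dose: np.ndarray, mask: np.ndarray, name: str = "structure") -> DVH:
    """Exact sort-based cumulative DVH of ``dose`` within ``mask``."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != np.shape(dose):
        raise ValueError("dose and mask shapes differ")
    if not mask.any():
        raise ValueError(f"structure {name!r} has an empty mask")
    return DVH(doses=np.sort(np.asarray(dose, dtype=float)[mask]))


def dose_at_volume(dvh: DVH, p: float) -> float:
    """Dp in Gy: the largest voxel dose received by at least p% of the volume."""
    if not 0 <= p <= 100:
        raise ValueError("p must be in [0, 100]")
    i = int(np.floor(dvh.n * (1.0 - p / 100.0)))
    return float(dvh.doses[min(max(i, 0), dvh.n - 1)])


def volume_at_dose(dvh: DVH, d: float) -> float:
    """Vd in percent: structure volume receiving at least d Gy."""
    return float(dvh.volume(d)) * 100.0


@dataclass(frozen=True)
class DVHIndexSet:
    """The 14 evaluation indices of one dose distribution.

    ``values`` maps ``(structure, index)`` in :data:`INDEX_ORDER` to Gy
    (D-type indices) or percent volume (V30).
    """

    values: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        if tuple(self.values) != INDEX_ORDER:
            raise ValueError("index set must contain exactly the 14 indices in order")
        v = self.values
        for s in ("bladder", "rectum"):
            if not 0.0 <= v[(s, "V30")] <= 100.0:
                raise ValueError(f"{s} V30 outside [0, 100]%")
        if v[("ptv", "Dmax")] + 1e-9 < v[("ptv", "D50")] or v[("ptv", "D50")] + 1e-9 < v[("ptv", "D95")]:
            raise ValueError("PTV indices violate Dmax >= D50 >= D95")

    def __getitem__(self, key: tuple[str, str]) -> float:
        return self.values[key]

    def as_array(self) -> np.ndarray:
        return np.array([self.values[k] for k in INDEX_ORDER])


def index_set(dose: np.ndarray, structures) -> DVHIndexSet:
    """Compute all 14 DVH indices; any required structure missing or empty
    is a hard error naming it."""
    structures.require(INDEX_STRUCTURES)
    values: dict[tuple[str, str], float] = {}
    dvhs = {
        s: cumulative_dvh(dose, structures[s], name=s) for s in INDEX_STRUCTURES
    }
    for struct, idx in INDEX_ORDER:
        dvh = dvhs[struct]
        if idx.startswith("D") and idx[1:].isdigit():
            values[(struct, idx)] = dose_at_volume(dvh, float(idx[1:]))
        elif idx == "Dmax":
            values[(struct, idx)] = float(dvh.doses[-1])
        elif idx == "Dmean":
            values[(struct, idx)] = float(dvh.doses.mean())
        elif idx.startswith("V"):
            values[(struct, idx)] = volume_at_dose(dvh, float(idx[1:]))
        else:  # pragma: no cover - INDEX_ORDER is fixed
            raise ValueError(f"unknown index {idx}")
    return DVHIndexSet(values=values)


@dataclass(frozen=True)
class ErrorReport:
    """Per-index delta errors of one predicted dose, in % of prescription.

    ``per_structure`` and the overall statistics are reported both ways
    the literature aggregates them: over indices within this case.
    """

    deltas: dict[tuple[str, str], float]
    prescription_gy: float
    per_structure: dict[str, tuple[float, float]] = field(default_factory=dict)
    overall_mean: float = 0.0
    overall_sd: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.deltas[k] for k in INDEX_ORDER])


def delta_errors(
    gt: DVHIndexSet, pred: DVHIndexSet, prescription_gy: float
) -> ErrorReport:
    """delta_i = |gt_i - pred_i| / prescription x 100 for each of the 14
    indices, with per-structure and overall mean/SD."""
    if prescription_gy <= 0:
        raise ValueError("prescription must be positive")
    deltas = {
        k: abs(gt[k] - pred[k]) / prescription_gy * 100.0 for k in INDEX_ORDER
    }
    per_structure = {}
    for s in INDEX_STRUCTURES:
        vals = np.array([d for (st, _), d in deltas.items() if st == s])
        per_structure[s] = (float(vals.mean()), float(vals.std()))
    arr = np.array(list(deltas.values()))
    return ErrorReport(
        deltas=deltas,
        prescription_gy=prescription_gy,
        per_structure=per_structure,
        overall_mean=float(arr.mean()),
        overall_sd=float(arr.std()),
    )


def mean_delta_by_index(reports: list[ErrorReport]) -> np.ndarray:
    """Mean delta per index across test cases, shape (14,)."""
    if not reports:
        raise ValueError("no error reports given")
    return np.stack([r.as_array() for r in reports]).mean(axis=0)


def best_model_fraction(
    reports_by_model: dict[str, list[ErrorReport]]
) -> dict[str, float]:
    """"% of best prediction" per model.

    For each of the 14 indices the per-model delta is first averaged over
    test cases; the model(s) attaining the smallest mean delta on an index
    are credited with it (ties credit every tied model).  The returned
    fraction is credited indices / 14.
    """
    if len(reports_by_model) < 2:
        raise ValueError("need at least two models to compare")
    n_cases = {m: len(r) for m, r in reports_by_model.items()}
    if len(set(n_cases.values())) != 1:
        raise ValueError(f"models evaluated on different case counts: {n_cases}")
    means = {m: mean_delta_by_index(r) for m, r in reports_by_model.items()}
    models = list(means)
    table = np.stack([means[m] for m in models])  # (n_models, 14)
    best = table.min(axis=0)
    credit = table <= best + 1e-12
    return {
        m: float(credit[i].sum()) / len(INDEX_ORDER) for i, m in enumerate(models)
    }
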