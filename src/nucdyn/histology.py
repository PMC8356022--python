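"""Histological quantification: nuclear displacement and synapse scoring.

Works on segmented-object tables, not images.  A nucleus is located
relative to the outer nuclear layer (ONL) by the local apical and basal
margins measured at its own tangential position; positions basal to the
basal margin (strictly) are "basally displaced", positions within the
margins (inclusive) are correctly localized, and the rare positions apical
to the apical margin are flagged separately as apically ectopic.

Synapse scoring tabulates pre-synaptic ribbon (ribeye) foci per rod cell —
shape (horseshoe vs punctate) and subcellular location (synaptic
bouton/process vs soma) are input labels — and scores pre/post-synaptic
apposition: a ribeye focus is apposed when at least one post-synaptic
mGluR6 punctum lies within 0.51 um (3-D centroid distance, inclusive).
Fractions are computed per cell and then averaged across cells, matching
per-cell reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ParameterError

__all__ = [
    "NucleusRecord",
    "RibeyeFocus",
    "SynapseCell",
    "SynapseSummary",
    "APPOSITION_RADIUS_UM",
    "relative_onl_position",
    "classify_displacement",
    "is_apically_ectopic",
    "displaced_density",
    "synapse_summary",
]

#: default centroid distance (um) under which ribeye and mGluR6 count as
#: apposed, i.e. a formed rod-bipolar synapse
APPOSITION_RADIUS_UM = 0.51

SHAPES = ("horseshoe", "punctate")
LOCATIONS = ("bouton_process", "soma")


@dataclass(frozen=True)
class NucleusRecord:
    """A segmented rod nucleus with its local ONL margins (um depth)."""

    nucleus_id: str
    x: float
    y: float
    z: float
    onl_apical: float
    onl_basal: float
    condition: str | None = None

    def __post_init__(self) -> None:
        if not self.onl_apical < self.onl_basal:
            raise ParameterError(
                f"nucleus {self.nucleus_id!r}: onl_apical must be < onl_basal"
            )
        if not np.isfinite(self.z):
            raise ParameterError(f"nucleus {self.nucleus_id!r}: non-finite z")


@dataclass(frozen=True)
class RibeyeFocus:
    """One pre-synaptic ribeye structure."""

    coords: tuple  # (x, y, z) um
    shape: str     # horseshoe | punctate
    location: str  # bouton_process | soma

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ParameterError(f"unknown ribeye shape {self.shape!r}")
        if self.location not in LOCATIONS:
            raise ParameterError(f"unknown ribeye location {self.location!r}")


@dataclass(frozen=True)
class SynapseCell:
    """All ribeye foci and mGluR6 puncta attributed to one rod cell."""

    cell_id: str
    ribeye_foci: tuple  # of RibeyeFocus
    mglur6_puncta: np.ndarray  # (M, 3) um; empty allowed
    displaced: bool = False


@dataclass(frozen=True)
class SynapseSummary:
    """Per-cell synapse organization summary (means across cells)."""

    n_cells: int
    foci_per_cell: np.ndarray            # per-cell counts (all cells)
    mean_foci_per_cell: float
    sd_foci_per_cell: float
    horseshoe_fraction: float            # mean per-cell fraction
    bouton_fraction: float               # mean per-cell fraction
    apposition_probability: float        # mean per-cell apposed fraction
    apposition_by_shape: dict            # shape -> mean per-cell fraction
    apposition_radius: float


def relative_onl_position(record: NucleusRecord) -> float:
    """Nuclear depth as percent of local ONL thickness.

    0% at the apical margin, 100% at the basal margin; values outside
    [0, 100] indicate positions beyond the ONL.
    """
    width = record.onl_basal - record.onl_apical
    if width <= 0:
        raise ParameterError("zero-width ONL")
    return 100.0 * (record.z - record.onl_apical) / width


def classify_displacement(record: NucleusRecord) -> str:
    """'displaced' iff strictly basal to the basal ONL margin, else 'correct'.

    Margins are inclusive on the correct side; apical positions are not
    "basally displaced" (see :func:`is_apically_ectopic`).
    """
    return "displaced" if record.z > record.onl_basal else "correct"


def is_apically_ectopic(record: NucleusRecord) -> bool:
    """True when the nucleus sits strictly apical to the apical ONL margin."""
    return record.z < record.onl_apical


def displaced_density(
    records: Iterable[NucleusRecord],
    field_area: float,
    area_unit: str = "1000um2",
) -> float:
    """Displaced nuclei per unit en-face area.

    ``field_area`` is in um^2; ``area_unit`` selects the reporting unit,
    per 1000 um^2 or per mm^2 (the two differ by exactly 1000).
    """
    if field_area <= 0:
        raise ParameterError("field_area must be positive")
    scale = {"1000um2": 1e3, "mm2": 1e6}.get(area_unit)
    if scale is None:
        raise ParameterError(f"unknown area unit {area_unit!r}")
    n_displaced = sum(
        1 for rec in records if classify_displacement(rec) == "displaced"
    )
    return n_displaced / field_area * scale


def _apposed(focus: RibeyeFocus, puncta: np.ndarray, radius: float) -> bool:
    if puncta.size == 0:
        return False
    d = np.linalg.norm(puncta - np.asarray(focus.coords), axis=1)
    return bool(np.min(d) <= radius)


def synapse_summary(
    cells: Sequence[SynapseCell],
    apposition_radius: float = APPOSITION_RADIUS_UM,
) -> SynapseSummary:
    """Tabulate ribeye organization and ribeye/mGluR6 apposition.

    Cells contribute their focus count always; cells with zero foci are
    excluded from shape, location and apposition denominators.  All
    fractions are per-cell fractions averaged across contributing cells.
    """
    if apposition_radius <= 0:
        raise ParameterError("apposition_radius must be positive")
    if not cells:
        raise ParameterError("no cells to summarize")
    counts = np.array([len(c.ribeye_foci) for c in cells], dtype=float)

    horseshoe, bouton, appo = [], [], []
    appo_shape: dict[str, list] = {s: [] for s in SHAPES}
    for cell in cells:
        foci = cell.ribeye_foci
        if not foci:
            continue
        horseshoe.append(
            np.mean([f.shape == "horseshoe" for f in foci])
        )
        bouton.append(
            np.mean([f.location == "bouton_process" for f in foci])
        )
        flags = [
            _apposed(f, cell.mglur6_puncta, apposition_radius) for f in foci
        ]
        appo.append(np.mean(flags))
        for shape in SHAPES:
            sel = [fl for f, fl in zip(foci, flags) if f.shape == shape]
            if sel:
                appo_shape[shape].append(np.mean(sel))

    return SynapseSummary(
        n_cells=len(cells),
        foci_per_cell=counts,
        mean_foci_per_cell=float(counts.mean()),
        sd_foci_per_cell=float(counts.std(ddof=1)) if counts.size > 1 else 0.0,
        horseshoe_fraction=float(np.mean(horseshoe)) if horseshoe else np.nan,
        bouton_fraction=float(np.mean(bouton)) if bouton else np.nan,
        apposition_probability=float(np.mean(appo)) if appo else np.nan,
        apposition_by_shape={
            s: (float(np.mean(v)) if v else np.nan)
            for s, v in appo_shape.items()
        },
        apposition_radius=float(apposition_radius),
    )
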