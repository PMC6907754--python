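"""Domain types and I/O for plant-pollinator survey and network tables.

The data backbone of the pipeline: validated record types for the three
survey tables (encounter events, weekly flower surveys, visits-per-encounter
follows), the plant trait table, and the :class:`WeightedBipartiteNetwork`
container that every descriptor consumes.

On-disk convention is long (tidy) CSV throughout: sparse field data and the
usual supplementary-deposit layout favour one row per cell over a matrix
grid. Zero-strength cells are treated as absent links everywhere; weighted
descriptors in this package never distinguish an observed zero from a
structural absence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "ValidationError",
    "EncounterEvent",
    "FlowerSurveyRecord",
    "VisitSample",
    "VisitEstimate",
    "PlantTraits",
    "WeightedBipartiteNetwork",
    "read_survey_tables",
    "read_plant_traits",
    "read_strength_matrix",
    "write_network",
]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A parsed value violates a record invariant."""


PROVENANCE_CLASSES = ("observed", "donor", "expert", "excluded")


@dataclass(frozen=True)
class EncounterEvent:
    """One pollinator individual observed on one plant individual in one week.

    Bee sexes are distinct pollinator labels (they differ in resource use and
    hence flower choice); `week` is a plain survey-week index starting at 1.
    """

    week: int
    plant: str
    pollinator: str

    def __post_init__(self) -> None:
        if self.week < 1:
            raise ValidationError(f"week must be >= 1, got {self.week}")
        if not self.plant or not self.pollinator:
            raise ValidationError("plant and pollinator labels must be non-empty")


@dataclass(frozen=True)
class FlowerSurveyRecord:
    """Weekly flower counts for one plant species.

    `flowers_surveyed` counts open flowers on the tagged, observed individuals
    that week (the denominator of weekly encounter frequency);
    `flower_abundance` is the plot-level weekly flower density (flowers/m^2
    from transect counts), the weighting factor of encounter strength.
    """

    week: int
    plant: str
    flowers_surveyed: int
    flower_abundance: float

    def __post_init__(self) -> None:
        if self.week < 1:
            raise ValidationError(f"week must be >= 1, got {self.week}")
        if not self.plant:
            raise ValidationError("plant label must be non-empty")
        if self.flowers_surveyed < 0:
            raise ValidationError(
                f"flowers_surveyed must be >= 0, got {self.flowers_surveyed}"
            )
        if self.flower_abundance < 0:
            raise ValidationError(
                f"flower_abundance must be >= 0, got {self.flower_abundance}"
            )


@dataclass(frozen=True)
class VisitSample:
    """Flowers (inflorescences in Asteraceae) visited in one 4-minute follow."""

    plant: str
    pollinator: str
    n_visits: int

    def __post_init__(self) -> None:
        if not self.plant or not self.pollinator:
            raise ValidationError("plant and pollinator labels must be non-empty")
        if self.n_visits < 1:
            raise ValidationError(
                f"n_visits >= 1 required (a recorded encounter involves at "
                f"least one flower), got {self.n_visits}"
            )


@dataclass(frozen=True)
class VisitEstimate:
    """Mean visits-per-encounter for one interaction, with provenance.

    Provenance records how the estimate was obtained: directly observed
    follows, a donor (functionally similar) pollinator on the same plant, an
    expert default, or `excluded` when no evidence-based estimate exists (an
    excluded interaction is dropped from all downstream analyses and its
    `mean_visits` is None).
    """

    plant: str
    pollinator: str
    mean_visits: float | None
    n_obs: int
    provenance: str

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCE_CLASSES:
            raise ValidationError(
                f"provenance must be one of {PROVENANCE_CLASSES}, "
                f"got {self.provenance!r}"
            )
        if self.provenance == "excluded":
            if self.mean_visits is not None:
                raise ValidationError("excluded interactions carry no mean_visits")
        else:
            if self.mean_visits is None or self.mean_visits <= 0:
                raise ValidationError(
                    f"mean_visits must be positive for provenance="
                    f"{self.provenance}, got {self.mean_visits}"
                )
        if self.provenance == "observed" and self.n_obs < 1:
            raise ValidationError("observed estimates require n_obs >= 1")

    @property
    def excluded(self) -> bool:
        return self.provenance == "excluded"


@dataclass(frozen=True)
class PlantTraits:
    """Per-plant floral display: mean open flowers per individual at peak bloom."""

    plant: str
    floral_display: float

    def __post_init__(self) -> None:
        if not self.plant:
            raise ValidationError("plant label must be non-empty")
        if not self.floral_display > 0:
            raise ValidationError(
                f"floral_display must be > 0, got {self.floral_display}"
            )


def _sorted_labels(totals: Mapping[str, float]) -> list[str]:
    # descending marginal total, alphabetical tie-break: deterministic order
    # for nestedness-style metrics that expect a sorted matrix
    return sorted(totals, key=lambda s: (-totals[s], s))


@dataclass(frozen=True)
class WeightedBipartiteNetwork:
    """Plants x pollinators matrix of nonnegative interaction strengths.

    Rows are plants, columns pollinators, both ordered by descending marginal
    total with alphabetical tie-break. Species without any retained positive
    cell are removed at construction, so every row and column total is
    strictly positive. `measure` tags the strength currency ("encounter" or
    "visit").
    """

    plants: tuple[str, ...]
    pollinators: tuple[str, ...]
    values: np.ndarray  # shape (len(plants), len(pollinators))
    measure: str = "encounter"

    def __post_init__(self) -> None:
        w = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", w)
        if w.ndim != 2 or w.shape != (len(self.plants), len(self.pollinators)):
            raise ValidationError("values shape must match label lists")
        if w.size == 0:
            raise ValidationError("network must contain at least one link")
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ValidationError("interaction strengths must be finite and >= 0")
        if np.any(w.sum(axis=1) <= 0) or np.any(w.sum(axis=0) <= 0):
            raise ValidationError(
                "all-zero row or column: species without retained interactions "
                "must be removed (use from_cells)"
            )
        w.setflags(write=False)

    # -- construction ----------------------------------------------------

    @classmethod
    def from_cells(
        cls,
        cells: Mapping[tuple[str, str], float],
        measure: str = "encounter",
    ) -> "WeightedBipartiteNetwork":
        """Build a network from a {(plant, pollinator): strength} mapping.

        Zero-strength cells are dropped; species left without any positive
        cell are removed; rows/columns are sorted canonically.
        """
        pos = {k: float(v) for k, v in cells.items() if v != 0}
        for (p, z), v in pos.items():
            if v < 0:
                raise ValidationError(f"negative strength for ({p}, {z}): {v}")
        if not pos:
            raise ValidationError("no positive interaction strengths: empty network")
        row_tot: dict[str, float] = {}
        col_tot: dict[str, float] = {}
        for (p, z), v in pos.items():
            row_tot[p] = row_tot.get(p, 0.0) + v
            col_tot[z] = col_tot.get(z, 0.0) + v
        plants = _sorted_labels(row_tot)
        polls = _sorted_labels(col_tot)
        w = np.zeros((len(plants), len(polls)))
        pi = {p: i for i, p in enumerate(plants)}
        zi = {z: j for j, z in enumerate(polls)}
        for (p, z), v in pos.items():
            w[pi[p], zi[z]] = v
        return cls(tuple(plants), tuple(polls), w, measure)

    @classmethod
    def from_long(
        cls, df: pd.DataFrame, strength_col: str = "strength", measure: str = "encounter"
    ) -> "WeightedBipartiteNetwork":
        cells: dict[tuple[str, str], float] = {}
        for row in df.itertuples(index=False):
            key = (str(getattr(row, "plant")), str(getattr(row, "pollinator")))
            cells[key] = cells.get(key, 0.0) + float(getattr(row, strength_col))
        return cls.from_cells(cells, measure=measure)

    # -- views ------------------------------------------------------------

    @property
    def plant_totals(self) -> np.ndarray:
        """Row marginal totals A_i."""
        return self.values.sum(axis=1)

    @property
    def pollinator_totals(self) -> np.ndarray:
        """Column marginal totals A_j."""
        return self.values.sum(axis=0)

    @property
    def total(self) -> float:
        """Grand total m = sum of all interaction strengths."""
        return float(self.values.sum())

    @property
    def n_links(self) -> int:
        return int(np.count_nonzero(self.values))

    def links(self) -> set[tuple[str, str]]:
        ii, jj = np.nonzero(self.values)
        return {(self.plants[i], self.pollinators[j]) for i, j in zip(ii, jj)}

    def cells(self) -> dict[tuple[str, str], float]:
        ii, jj = np.nonzero(self.values)
        return {
            (self.plants[i], self.pollinators[j]): float(self.values[i, j])
            for i, j in zip(ii, jj)
        }

    def to_long(self) -> pd.DataFrame:
        ii, jj = np.nonzero(self.values)
        return pd.DataFrame(
            {
                "plant": [self.plants[i] for i in ii],
                "pollinator": [self.pollinators[j] for j in jj],
                "strength": self.values[ii, jj],
            }
        )

    # -- derived networks --------------------------------------------------

    def drop_links(self, pairs: Iterable[tuple[str, str]]) -> "WeightedBipartiteNetwork":
        """Remove the given (plant, pollinator) links, re-validating margins."""
        drop = set(pairs)
        cells = {k: v for k, v in self.cells().items() if k not in drop}
        return WeightedBipartiteNetwork.from_cells(cells, measure=self.measure)

    def scaled(self, c: float) -> "WeightedBipartiteNetwork":
        if c <= 0:
            raise ValidationError("scale factor must be positive")
        return WeightedBipartiteNetwork(
            self.plants, self.pollinators, self.values * c, self.measure
        )

    def same_cells(self, other: "WeightedBipartiteNetwork", rtol: float = 0.0) -> bool:
        a, b = self.cells(), other.cells()
        if a.keys() != b.keys():
            return False
        return all(np.isclose(a[k], b[k], rtol=rtol, atol=0.0) for k in a)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_table(
    path: str | Path,
    required: Sequence[str],
    columns: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a delimited table, renaming via `columns` (canonical -> file name).

    Unknown columns are ignored with a logged warning; a missing required
    column raises :class:`SchemaError` naming it.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if columns:
        df = df.rename(columns={v: k for k, v in columns.items()})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        logger.warning("%s: ignoring unknown column(s) %s", path, extra)
    return df[list(required)]


def _build_records(df: pd.DataFrame, factory, path) -> list:
    out = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        try:
            out.append(factory(row))
        except (ValidationError, ValueError, TypeError) as exc:
            raise ValidationError(f"{path}, row {idx}: {exc}") from exc
    return out


def read_survey_tables(
    encounters_path: str | Path,
    flowers_path: str | Path,
    visits_path: str | Path,
    *,
    encounter_columns: Mapping[str, str] | None = None,
    flower_columns: Mapping[str, str] | None = None,
    visit_columns: Mapping[str, str] | None = None,
) -> tuple[list[EncounterEvent], list[FlowerSurveyRecord], list[VisitSample]]:
    """Parse and validate the three survey CSVs.

    Expected headers (remappable through the ``*_columns`` arguments, given as
    canonical-name -> file-column-name): ``week,plant,pollinator`` for
    encounters; ``week,plant,flowers_surveyed,flower_abundance`` for flower
    surveys; ``plant,pollinator,n_visits`` for 4-minute follows. Duplicate
    (week, plant) flower rows are rejected.
    """
    enc_df = _read_table(encounters_path, ["week", "plant", "pollinator"], encounter_columns)
    encounters = _build_records(
        enc_df,
        lambda r: EncounterEvent(int(r.week), str(r.plant), str(r.pollinator)),
        encounters_path,
    )

    flo_df = _read_table(
        flowers_path,
        ["week", "plant", "flowers_surveyed", "flower_abundance"],
        flower_columns,
    )
    dup = flo_df.duplicated(subset=["week", "plant"], keep=False)
    if dup.any():
        pairs = flo_df.loc[dup, ["week", "plant"]].drop_duplicates()
        raise ValidationError(
            f"{flowers_path}: duplicate (week, plant) flower rows: "
            + ", ".join(f"({r.week}, {r.plant})" for r in pairs.itertuples())
        )
    flowers = _build_records(
        flo_df,
        lambda r: FlowerSurveyRecord(
            int(r.week), str(r.plant), int(r.flowers_surveyed), float(r.flower_abundance)
        ),
        flowers_path,
    )

    vis_df = _read_table(visits_path, ["plant", "pollinator", "n_visits"], visit_columns)
    visits = _build_records(
        vis_df,
        lambda r: VisitSample(str(r.plant), str(r.pollinator), int(r.n_visits)),
        visits_path,
    )
    return encounters, flowers, visits


def read_plant_traits(
    path: str | Path, columns: Mapping[str, str] | None = None
) -> list[PlantTraits]:
    """Read the plant trait table (header ``plant,floral_display``)."""
    df = _read_table(path, ["plant", "floral_display"], columns)
    return _build_records(
        df, lambda r: PlantTraits(str(r.plant), float(r.floral_display)), path
    )


def read_strength_matrix(
    path: str | Path,
    measure: str = "encounter",
    columns: Mapping[str, str] | None = None,
) -> WeightedBipartiteNetwork:
    """Read a long-format strength matrix into a network.

    The file carries columns ``plant,pollinator`` and one strength column per
    measure (``strength_encounter`` and/or ``strength_visit``; a bare
    ``strength`` column is accepted for single-measure files). Deposited
    supplementary tables with other column names are handled through
    ``columns`` (canonical -> file name). Zero-strength rows are dropped.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if columns:
        df = df.rename(columns={v: k for k, v in columns.items()})
    for c in ("plant", "pollinator"):
        if c not in df.columns:
            raise SchemaError(f"{path}: missing required column(s) ['{c}']")
    strength_col = None
    for cand in (f"strength_{measure}", "strength"):
        if cand in df.columns:
            strength_col = cand
            break
    if strength_col is None:
        raise SchemaError(
            f"{path}: no strength column for measure {measure!r} "
            f"(expected 'strength_{measure}' or 'strength')"
        )
    if df.empty:
        raise ValidationError(f"{path}: empty strength matrix file")
    s = pd.to_numeric(df[strength_col], errors="raise")
    neg = s < 0
    if neg.any():
        raise ValidationError(
            f"{path}: negative strength at row(s) {list(df.index[neg] + 2)}"
        )
    df = df.assign(**{strength_col: s})
    return WeightedBipartiteNetwork.from_long(df, strength_col, measure=measure)


def write_network(network: WeightedBipartiteNetwork, path: str | Path) -> None:
    """Write a network as a long CSV; round-trips exactly through
    :func:`read_strength_matrix`."""
    df = network.to_long().rename(
        columns={"strength": f"strength_{network.measure}"}
    )
    if df.empty:  # unreachable for a valid network; guard anyway
        raise ValidationError("refusing to write an empty network")
    df.to_csv(path, index=False)
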