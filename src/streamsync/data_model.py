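"""Capture-history data model for open-population mark-recapture analysis.

Encounter records (one row per detection of a tagged individual on a
sampling occasion) are assembled into a binary individuals-by-occasions
capture-history matrix, the sufficient data object for Cormack-Jolly-Seber
(CJS) survival models.  Occasions are 1-based in every public interface;
internal arrays are 0-based but never exposed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

ENCOUNTER_COLUMNS = ("id", "species", "stream", "occasion", "detected")


@dataclasses.dataclass(frozen=True)
class SpeciesStreamIndex:
    """Registry fixing the order of species and stream labels.

    Parameter vectors are indexed by position in these tuples, so the order
    must come from an explicit declaration (e.g. the scenario config), not
    from whatever order labels happen to appear in a data file.
    """

    species_labels: tuple[str, ...]
    stream_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        for name, labels in (("species", self.species_labels),
                             ("stream", self.stream_labels)):
            if len(labels) != len(set(labels)):
                raise ValueError(f"duplicate {name} labels: {labels}")
            if len(labels) == 0:
                raise ValueError(f"empty {name} label list")
        object.__setattr__(self, "species_labels", tuple(self.species_labels))
        object.__setattr__(self, "stream_labels", tuple(self.stream_labels))

    @property
    def n_species(self) -> int:
        return len(self.species_labels)

    @property
    def n_streams(self) -> int:
        return len(self.stream_labels)

    @property
    def n_groups(self) -> int:
        return self.n_species * self.n_streams

    def species_pos(self, label: str) -> int:
        """0-based position of a species label."""
        try:
            return self.species_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown species label {label!r}; "
                           f"registered: {self.species_labels}") from None

    def stream_pos(self, label: str) -> int:
        """0-based position of a stream label."""
        try:
            return self.stream_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown stream label {label!r}; "
                           f"registered: {self.stream_labels}") from None

    def group_of(self, species: str, stream: str) -> int:
        """1-based group number on the species-by-stream grid."""
        return self.species_pos(species) * self.n_streams + self.stream_pos(stream) + 1

    def group_labels(self) -> list[tuple[str, str]]:
        """(species, stream) label pairs in group order."""
        return [(sp, st) for sp in self.species_labels for st in self.stream_labels]


@dataclasses.dataclass(frozen=True, eq=False)
class OccasionCalendar:
    """Median sampling day of each occasion and the interval lengths.

    ``n_days[t]`` is the number of days between the median sampling day of
    occasion t and occasion t+1 (1-based t = 1..T-1); it drives the 60-day
    standardization of survival.
    """

    occasion_dates: pd.DatetimeIndex

    def __post_init__(self) -> None:
        dates = pd.DatetimeIndex(self.occasion_dates)
        object.__setattr__(self, "occasion_dates", dates)
        if len(dates) < 2:
            raise ValueError("calendar needs at least 2 occasions")
        if not dates.is_monotonic_increasing or dates.has_duplicates:
            raise ValueError("occasion dates must be strictly increasing")

    @property
    def n_occasions(self) -> int:
        return len(self.occasion_dates)

    @property
    def n_days(self) -> np.ndarray:
        """Integer day counts between consecutive median sampling days."""
        deltas = np.diff(self.occasion_dates.values).astype("timedelta64[D]")
        return deltas.astype(np.int64)

    def equals(self, other: "OccasionCalendar") -> bool:
        return self.occasion_dates.equals(other.occasion_dates)


@dataclasses.dataclass(eq=False)
class CaptureHistoryMatrix:
    """Binary detection matrix y[i, t] with individual metadata.

    ``individuals`` holds one row per matrix row with columns ``id``,
    ``species``, ``stream``, ``first_capture`` (1-based occasion) and
    ``terminal_only`` (True when the individual was first captured on the
    final occasion and therefore contributes no survival information to a
    CJS likelihood, which conditions on first capture).
    """

    detections: np.ndarray
    individuals: pd.DataFrame
    calendar: OccasionCalendar
    index: SpeciesStreamIndex

    def __post_init__(self) -> None:
        self.detections = np.asarray(self.detections, dtype=np.int8)
        self.validate()

    def validate(self) -> None:
        y = self.detections
        T = self.calendar.n_occasions
        if y.ndim != 2 or y.shape[1] != T:
            raise ValueError(f"detections must be (n, {T}), got {y.shape}")
        if y.shape[0] != len(self.individuals):
            raise ValueError("individuals table does not match detection rows")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("detections must be 0/1")
        if not (y.sum(axis=1) >= 1).all():
            raise ValueError("every capture history must contain a detection")
        first = np.argmax(y == 1, axis=1)  # 0-based
        fc = self.individuals["first_capture"].to_numpy()
        if not np.array_equal(first + 1, fc):
            raise ValueError("first_capture column inconsistent with matrix")
        for label in self.individuals["species"].unique():
            self.index.species_pos(label)
        for label in self.individuals["stream"].unique():
            self.index.stream_pos(label)

    @property
    def n_individuals(self) -> int:
        return self.detections.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.calendar.n_occasions

    def species_codes(self) -> np.ndarray:
        """0-based species position per individual."""
        lut = {s: i for i, s in enumerate(self.index.species_labels)}
        return self.individuals["species"].map(lut).to_numpy(dtype=np.int64)

    def stream_codes(self) -> np.ndarray:
        """0-based stream position per individual."""
        lut = {s: i for i, s in enumerate(self.index.stream_labels)}
        return self.individuals["stream"].map(lut).to_numpy(dtype=np.int64)

    def group_codes(self) -> np.ndarray:
        """0-based species-by-stream group per individual."""
        return self.species_codes() * self.index.n_streams + self.stream_codes()

    def to_long(self) -> pd.DataFrame:
        """Long-format dump: one encounter record per detection."""
        rows, cols = np.nonzero(self.detections)
        info = self.individuals.iloc[rows]
        return pd.DataFrame({
            "id": info["id"].to_numpy(),
            "species": info["species"].to_numpy(),
            "stream": info["stream"].to_numpy(),
            "occasion": cols + 1,
            "detected": 1,
        })


def build_capture_histories(records: pd.DataFrame, calendar: OccasionCalendar,
                            index: SpeciesStreamIndex) -> CaptureHistoryMatrix:
    """Assemble a capture-history matrix from long-format encounter records.

    Multiple detections of one individual within an occasion (e.g. the two
    electrofishing passes) collapse to a single 1.  Rows are ordered by id.
    Conflicting species or stream labels for one id are a hard error.
    """
    missing = [c for c in ENCOUNTER_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"encounter records missing columns: {missing}")
    T = calendar.n_occasions
    occ = records["occasion"].to_numpy()
    if ((occ < 1) | (occ > T)).any():
        bad = sorted(set(occ[(occ < 1) | (occ > T)]))
        raise ValueError(f"occasions outside calendar 1..{T}: {bad}")

    for col in ("species", "stream"):
        per_id = records.groupby("id", sort=False)[col].nunique()
        conflicts = per_id[per_id > 1]
        if len(conflicts):
            raise ValueError(
                f"conflicting {col} labels for ids: {list(conflicts.index)}")

    detected = records[records["detected"].astype(int) == 1]
    all_ids = pd.unique(records["id"])
    seen_ids = set(detected["id"])
    ghosts = [i for i in all_ids if i not in seen_ids]
    if ghosts:
        raise ValueError(f"ids with no positive detection: {ghosts}")

    ids = np.sort(pd.unique(detected["id"]))
    row_of = {i: r for r, i in enumerate(ids)}
    y = np.zeros((len(ids), T), dtype=np.int8)
    rr = detected["id"].map(row_of).to_numpy()
    y[rr, detected["occasion"].to_numpy() - 1] = 1

    meta = (detected.drop_duplicates("id")[["id", "species", "stream"]]
            .set_index("id").loc[ids].reset_index())
    first = np.argmax(y == 1, axis=1) + 1
    meta["first_capture"] = first
    meta["terminal_only"] = first == T
    return CaptureHistoryMatrix(y, meta, calendar, index)


def summarize_cohort(matrix: CaptureHistoryMatrix) -> pd.DataFrame:
    """Tagged counts per species-by-stream group (zero-count groups kept)."""
    counts = (matrix.individuals.groupby(["species", "stream"], sort=False)
              .size().to_dict())
    rows = [{"species": sp, "stream": st, "n_tagged": counts.get((sp, st), 0)}
            for sp, st in matrix.index.group_labels()]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Delimited-text IO


def read_encounters(path) -> pd.DataFrame:
    """Read encounter records; extra columns are preserved but unused."""
    table = pd.read_csv(path)
    missing = [c for c in ENCOUNTER_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    table["id"] = table["id"].astype(str)
    return table


def write_encounters(table: pd.DataFrame, path) -> None:
    missing = [c for c in ENCOUNTER_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cannot write encounters, missing columns {missing}")
    table.to_csv(path, index=False)


def read_calendar(path) -> OccasionCalendar:
    table = pd.read_csv(path)
    for col in ("occasion", "median_date"):
        if col not in table.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    table = table.sort_values("occasion")
    if not np.array_equal(table["occasion"].to_numpy(),
                          np.arange(1, len(table) + 1)):
        raise ValueError(f"{path}: occasions must be contiguous 1..T")
    return OccasionCalendar(pd.DatetimeIndex(pd.to_datetime(table["median_date"])))


def write_calendar(calendar: OccasionCalendar, path) -> None:
    pd.DataFrame({
        "occasion": np.arange(1, calendar.n_occasions + 1),
        "median_date": calendar.occasion_dates.strftime("%Y-%m-%d"),
    }).to_csv(path, index=False)


def write_capture_histories(matrix: CaptureHistoryMatrix, path) -> None:
    """Compact dump: one row per individual with a T-character 0/1 string."""
    h = ["".join(map(str, row)) for row in matrix.detections]
    out = matrix.individuals[["id", "species", "stream"]].copy()
    out["h"] = h
    out.to_csv(path, index=False)


def read_capture_histories(path, calendar: OccasionCalendar,
                           index: SpeciesStreamIndex) -> CaptureHistoryMatrix:
    table = pd.read_csv(path, dtype={"h": str})
    for col in ("id", "species", "stream", "h"):
        if col not in table.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    y = np.array([[int(c) for c in h] for h in table["h"]], dtype=np.int8)
    meta = table[["id", "species", "stream"]].copy()
    meta["id"] = meta["id"].astype(str)
    first = np.argmax(y == 1, axis=1) + 1
    meta["first_capture"] = first
    meta["terminal_only"] = first == calendar.n_occasions
    return CaptureHistoryMatrix(y, meta, calendar, index)
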