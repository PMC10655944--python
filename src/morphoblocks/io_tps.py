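"""Reading and writing TPS landmark files and specimen metadata tables.

The TPS format (as written by the tps series of digitising programs) stores one
landmark configuration per record: an ``LM=k`` header followed by ``k`` lines of
``x y`` coordinates, optionally followed by ``ID=``, ``IMAGE=``, ``SCALE=`` and
``COMMENT=`` lines.  Coordinates are taken y-up, exactly as stored; any
image-axis flip is the digitiser's concern.

Specimen metadata (sex, diploid number, karyotypic block, chromosomal pair
states, locality and coordinates) travels as a CSV table with a header row.
Karyotypic blocks are geographic subpopulations defined by their diploid
numbers; the block/karyotype consistency map is enforced on read.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

VIEWS = ("dorsal", "ventral", "lateral")

#: Default landmark counts per cranial view.
DEFAULT_K = {"dorsal": 29, "ventral": 30, "lateral": 21}

#: Diploid numbers allowed within each karyotypic block.  2n = 54 occurs in
#: two blocks and is encoded as the distinct tokens 54A / 54C so the two
#: populations can be compared.
BLOCK_KARYOTYPES = {
    "A": ("54A", "55a", "56a"),
    "B": ("57", "58"),
    "C": ("54C", "55a"),
    "D": ("55b", "56b"),
}

KARYOTYPES = tuple(sorted({k for v in BLOCK_KARYOTYPES.values() for k in v}))
SEXES = ("F", "M")
PAIR_STATES = ("MM", "MA", "AA")


class TpsParseError(ValueError):
    """Raised when a TPS file cannot be parsed."""


class ValidationError(ValueError):
    """Raised when parsed data violate a dataset invariant."""


@dataclass
class LandmarkConfiguration:
    """One specimen's 2D landmark configuration for one cranial view.

    Parameters
    ----------
    specimen_id : str
        Identifier linking the configuration to its metadata record.
    view : str
        One of ``dorsal``, ``ventral``, ``lateral``.
    coords : (k, 2) ndarray
        Landmark coordinates in consistent units, fixed landmark order.
    scale : float, optional
        Units-per-pixel factor already applied to ``coords`` (recorded for
        provenance; ``None`` when the file carried no SCALE line).
    """

    specimen_id: str
    view: str
    coords: np.ndarray
    scale: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValidationError(
                f"coords must be (k, 2), got {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError(
                f"non-finite coordinate in configuration {self.specimen_id!r}"
            )
        if self.view not in VIEWS:
            raise ValidationError(f"unknown view {self.view!r}")

    @property
    def k(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class SpecimenRecord:
    """Metadata for one specimen: sex, karyotype, block, locality."""

    specimen_id: str
    sex: str
    diploid_2n: str
    block: str
    pair1: str | None = None
    pair2: str | None = None
    locality_id: int | None = None
    lat: float | None = None
    lon: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(
                f"{self.specimen_id}: unknown sex {self.sex!r}"
            )
        if self.block not in BLOCK_KARYOTYPES:
            raise ValidationError(
                f"{self.specimen_id}: unknown block {self.block!r}"
            )
        if self.diploid_2n not in KARYOTYPES:
            raise ValidationError(
                f"{self.specimen_id}: unknown karyotype {self.diploid_2n!r}"
            )
        if self.diploid_2n not in BLOCK_KARYOTYPES[self.block]:
            raise ValidationError(
                f"{self.specimen_id}: karyotype 2n={self.diploid_2n} is not "
                f"found in block {self.block} "
                f"(allowed: {BLOCK_KARYOTYPES[self.block]})"
            )
        for name, state in (("pair1", self.pair1), ("pair2", self.pair2)):
            if state is not None and state not in PAIR_STATES:
                raise ValidationError(
                    f"{self.specimen_id}: invalid {name} state {state!r}"
                )
        if self.lat is not None and not -90.0 <= self.lat <= 90.0:
            raise ValidationError(f"{self.specimen_id}: latitude out of range")
        if self.lon is not None and not -180.0 <= self.lon <= 180.0:
            raise ValidationError(f"{self.specimen_id}: longitude out of range")

    @property
    def has_coordinates(self) -> bool:
        return self.lat is not None and self.lon is not None


@dataclass(frozen=True)
class PairMap:
    """Bilateral landmark pairing for one view.

    ``pairs`` holds 0-based (left, right) index pairs; ``midline`` the 0-based
    indices of unpaired (sagittal) landmarks.  Together they must partition
    ``0..k-1``.  The on-disk format is 1-based to match anatomical landmark
    numbering.
    """

    pairs: tuple[tuple[int, int], ...]
    midline: tuple[int, ...]

    def __post_init__(self) -> None:
        seen: list[int] = []
        for a, b in self.pairs:
            seen.extend((a, b))
        seen.extend(self.midline)
        if len(seen) != len(set(seen)):
            raise ValidationError("pair map indices are not disjoint")
        if seen and (min(seen) < 0):
            raise ValidationError("pair map indices must be >= 0")

    @property
    def k(self) -> int:
        return 2 * len(self.pairs) + len(self.midline)

    def validate_for(self, k: int) -> None:
        if self.k != k:
            raise ValidationError(
                f"pair map covers {self.k} landmarks, configuration has {k}"
            )
        indices = sorted(
            [i for p in self.pairs for i in p] + list(self.midline)
        )
        if indices != list(range(k)):
            raise ValidationError(
                "pair map must partition landmark indices 0..k-1"
            )

    def permutation(self) -> np.ndarray:
        """Index permutation swapping left/right labels (midline fixed)."""
        perm = np.arange(self.k)
        for a, b in self.pairs:
            perm[a], perm[b] = b, a
        return perm


@dataclass
class MorphometricDataset:
    """A validated multi-view landmark dataset with metadata.

    ``configurations`` maps ``(specimen_id, view)`` to a configuration,
    ``records`` maps ``specimen_id`` to its metadata, and ``pair_maps`` holds
    the bilateral pairing per view (views without bilateral landmarks, such as
    the lateral view, simply list every landmark as midline).
    """

    configurations: dict[tuple[str, str], LandmarkConfiguration]
    records: dict[str, SpecimenRecord]
    pair_maps: dict[str, PairMap] = field(default_factory=dict)

    @property
    def views(self) -> tuple[str, ...]:
        return tuple(v for v in VIEWS
                     if any(key[1] == v for key in self.configurations))

    def ids(self, view: str | None = None) -> tuple[str, ...]:
        if view is None:
            return tuple(sorted(self.records))
        return tuple(sorted(i for (i, v) in self.configurations if v == view))

    @property
    def complete_ids(self) -> tuple[str, ...]:
        """Specimens present in every view of the dataset (sorted)."""
        views = self.views
        return tuple(
            i for i in sorted(self.records)
            if all((i, v) in self.configurations for v in views)
        )

    @property
    def incomplete_ids(self) -> tuple[str, ...]:
        complete = set(self.complete_ids)
        return tuple(i for i in sorted(self.records) if i not in complete)

    def coordinate_array(self, view: str,
                         ids: Sequence[str] | None = None) -> np.ndarray:
        """Stack configurations of one view into an (n, k, 2) array."""
        if ids is None:
            ids = self.ids(view)
        return np.stack([self.configurations[(i, view)].coords for i in ids])


_KEY_RE = re.compile(r"^\s*([A-Za-z]+)\s*=\s*(.*?)\s*$")


def read_tps(path: str | Path, view: str,
             expected_k: int | None = None) -> list[LandmarkConfiguration]:
    """Read every record of a TPS file as configurations of one view.

    Coordinates are multiplied by the record's SCALE factor when present.
    The specimen id is taken from the ID line, else the IMAGE basename, else a
    running record index.  All records must share the same landmark count;
    pass ``expected_k`` to additionally pin that count.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    configs: list[LandmarkConfiguration] = []
    i = 0
    record_index = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        m = _KEY_RE.match(line)
        if not m or m.group(1).upper() != "LM":
            raise TpsParseError(
                f"{path}: expected LM= header at line {i + 1}, got {line!r}"
            )
        try:
            k = int(m.group(2))
        except ValueError:
            raise TpsParseError(
                f"{path}: bad LM count at line {i + 1}: {m.group(2)!r}"
            ) from None
        i += 1
        coords = np.empty((k, 2))
        for j in range(k):
            if i >= len(lines):
                raise TpsParseError(
                    f"{path}: record {record_index} ends after "
                    f"{j} of {k} landmarks"
                )
            parts = lines[i].split()
            if len(parts) != 2 or _KEY_RE.match(lines[i].strip()):
                raise TpsParseError(
                    f"{path}: record {record_index} declares LM={k} but has "
                    f"only {j} coordinate lines (line {i + 1})"
                )
            try:
                coords[j] = [float(parts[0]), float(parts[1])]
            except ValueError:
                raise TpsParseError(
                    f"{path}: non-numeric coordinate at line {i + 1}: "
                    f"{lines[i]!r}"
                ) from None
            i += 1
        specimen_id: str | None = None
        image: str | None = None
        scale: float | None = None
        while i < len(lines):
            m = _KEY_RE.match(lines[i].strip())
            if not m:
                break
            key, value = m.group(1).upper(), m.group(2)
            if key == "LM":
                break
            if key == "ID":
                specimen_id = value
            elif key == "IMAGE":
                image = value
            elif key == "SCALE":
                try:
                    scale = float(value)
                except ValueError:
                    raise TpsParseError(
                        f"{path}: non-numeric SCALE at line {i + 1}"
                    ) from None
            elif key != "COMMENT":
                raise TpsParseError(
                    f"{path}: unknown key {key!r} at line {i + 1}"
                )
            i += 1
        if specimen_id is None:
            specimen_id = Path(image).stem if image else str(record_index)
        if scale is not None:
            coords = coords * scale
        configs.append(
            LandmarkConfiguration(specimen_id, view, coords, scale=scale)
        )
        record_index += 1
    ks = {c.k for c in configs}
    if len(ks) > 1:
        raise ValidationError(
            f"{path}: inconsistent landmark counts across records: {sorted(ks)}"
        )
    if expected_k is not None and configs and configs[0].k != expected_k:
        raise ValidationError(
            f"{path}: expected k={expected_k} landmarks, found {configs[0].k}"
        )
    return configs


def write_tps(path: str | Path,
              configs: Iterable[LandmarkConfiguration]) -> None:
    """Write configurations to a TPS file (one record per configuration).

    Coordinates are written as already scaled; no SCALE line is emitted, so a
    read/write round trip reproduces coordinates exactly.
    """
    out: list[str] = []
    for c in configs:
        out.append(f"LM={c.k}")
        for x, y in c.coords:
            out.append(f"{x:.10g} {y:.10g}")
        out.append(f"ID={c.specimen_id}")
    Path(path).write_text("\n".join(out) + "\n")


_TABLE_FIELDS = ("specimen_id", "sex", "diploid_2n", "block",
                 "pair1", "pair2", "locality_id", "lat", "lon")


def read_specimen_table(path: str | Path) -> list[SpecimenRecord]:
    """Read the specimen metadata CSV and validate every row.

    Empty pair1/pair2/locality/lat/lon cells yield ``None`` (such specimens
    are later excluded from analyses that need the missing field).
    """
    records: list[SpecimenRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValidationError(f"{path}: empty metadata table")
        missing = {"specimen_id", "sex", "diploid_2n", "block"} - set(
            reader.fieldnames
        )
        if missing:
            raise ValidationError(
                f"{path}: metadata table lacks columns {sorted(missing)}"
            )
        for row_no, row in enumerate(reader, start=2):
            sid = (row.get("specimen_id") or "").strip()
            if not sid:
                raise ValidationError(f"{path}: row {row_no}: empty specimen_id")
            if sid in seen:
                raise ValidationError(
                    f"{path}: row {row_no}: duplicate specimen_id {sid!r}"
                )
            seen.add(sid)

            def opt(name: str) -> str | None:
                v = (row.get(name) or "").strip()
                return v or None

            def opt_float(name: str) -> float | None:
                v = opt(name)
                if v is None:
                    return None
                try:
                    f = float(v)
                except ValueError:
                    raise ValidationError(
                        f"{path}: row {row_no}: non-numeric {name} {v!r}"
                    ) from None
                return None if math.isnan(f) else f

            loc = opt("locality_id")
            try:
                records.append(SpecimenRecord(
                    specimen_id=sid,
                    sex=(row.get("sex") or "").strip(),
                    diploid_2n=(row.get("diploid_2n") or "").strip(),
                    block=(row.get("block") or "").strip(),
                    pair1=opt("pair1"),
                    pair2=opt("pair2"),
                    locality_id=int(loc) if loc is not None else None,
                    lat=opt_float("lat"),
                    lon=opt_float("lon"),
                ))
            except ValidationError as e:
                raise ValidationError(f"{path}: row {row_no}: {e}") from None
    return records


def write_specimen_table(path: str | Path,
                         records: Iterable[SpecimenRecord]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_TABLE_FIELDS)
        for r in records:
            writer.writerow([
                r.specimen_id, r.sex, r.diploid_2n, r.block,
                r.pair1 or "", r.pair2 or "",
                "" if r.locality_id is None else r.locality_id,
                "" if r.lat is None else repr(r.lat),
                "" if r.lon is None else repr(r.lon),
            ])


def read_pair_map(path: str | Path) -> dict[str, PairMap]:
    """Read per-view bilateral pair maps from a small CSV config.

    Format: ``view,kind,indices`` rows where kind is ``pair`` (two 1-based
    indices separated by a space) or ``midline`` (one index). 1-based indexing
    matches anatomical landmark numbering.
    """
    pairs: dict[str, list[tuple[int, int]]] = {}
    midline: dict[str, list[int]] = {}
    with open(path, newline="") as fh:
        for row_no, row in enumerate(csv.reader(fh), start=1):
            if not row or row[0].startswith("#") or row[0] == "view":
                continue
            view, kind, idx = row[0].strip(), row[1].strip(), row[2].split()
            if kind == "pair":
                if len(idx) != 2:
                    raise ValidationError(
                        f"{path}: row {row_no}: pair needs two indices"
                    )
                pairs.setdefault(view, []).append(
                    (int(idx[0]) - 1, int(idx[1]) - 1)
                )
                midline.setdefault(view, [])
            elif kind == "midline":
                midline.setdefault(view, []).append(int(idx[0]) - 1)
                pairs.setdefault(view, [])
            else:
                raise ValidationError(
                    f"{path}: row {row_no}: unknown kind {kind!r}"
                )
    return {
        v: PairMap(tuple(pairs[v]), tuple(midline[v])) for v in pairs
    }


def write_pair_map(path: str | Path, pair_maps: Mapping[str, PairMap]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["view", "kind", "indices"])
        for view, pm in pair_maps.items():
            for a, b in pm.pairs:
                writer.writerow([view, "pair", f"{a + 1} {b + 1}"])
            for m in pm.midline:
                writer.writerow([view, "midline", str(m + 1)])


def assemble_dataset(
    configs_by_view: Mapping[str, Sequence[LandmarkConfiguration]],
    records: Sequence[SpecimenRecord],
    pair_maps: Mapping[str, PairMap] | None = None,
) -> MorphometricDataset:
    """Validate and assemble configurations plus metadata into one dataset.

    Every configuration must have a metadata record; per view, all
    configurations must share the landmark count and the pair map (when given)
    must partition its indices.  Specimens missing one or more views are kept
    (``incomplete_ids``); multi-view integration later uses ``complete_ids``.
    Assembly is keyed by id, hence independent of input file order.
    """
    record_map = {r.specimen_id: r for r in records}
    if len(record_map) != len(records):
        raise ValidationError("duplicate specimen_id in records")
    configurations: dict[tuple[str, str], LandmarkConfiguration] = {}
    for view, configs in configs_by_view.items():
        ks = {c.k for c in configs}
        if len(ks) > 1:
            raise ValidationError(
                f"view {view}: inconsistent landmark counts {sorted(ks)}"
            )
        for c in configs:
            if c.specimen_id not in record_map:
                raise ValidationError(
                    f"configuration {c.specimen_id!r} ({view}) has no "
                    "metadata record"
                )
            key = (c.specimen_id, view)
            if key in configurations:
                raise ValidationError(f"duplicate configuration for {key}")
            configurations[key] = c
    pair_maps = dict(pair_maps or {})
    for view, pm in pair_maps.items():
        ks = {c.k for c in configs_by_view.get(view, [])}
        if ks:
            pm.validate_for(ks.pop())
    return MorphometricDataset(configurations, record_map, pair_maps)
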