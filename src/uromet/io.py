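"""Readers and writers for the pipeline's external artifacts.

The pipeline exchanges five kinds of files:

* **spectra** — plain two-column text (ppm, intensity), one file per sample;
* **bucket schemes** — YAML descriptions of integration intervals on the
  ppm axis plus excluded regions (water, urea, the TSP reference);
* **bucket tables** — CSV/TSV matrices of samples x buckets with
  ``sample_id``/``group``/``week`` metadata columns, the central exchange
  object of the analysis;
* **annotation tables** — TSV mapping bucket ids to metabolite names;
* **metabolite-set libraries** — TSV mapping set ids to member metabolites,
  used for over-representation analysis.

All formats are deliberately plain text so that deposited datasets (binned
intensities exported from vendor bucketing tools) can be ingested with at
most a column-name remapping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from io import StringIO
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Spectrum",
    "Bucket",
    "BucketScheme",
    "BucketTable",
    "MetaboliteSetLibrary",
    "ParseError",
    "ValidationError",
    "CONTROL",
    "STUDY",
    "read_spectrum",
    "write_spectrum",
    "read_bucket_table",
    "write_bucket_table",
    "load_bucket_scheme",
    "save_bucket_scheme",
    "read_annotation",
    "read_metabolite_sets",
]

#: canonical group labels: ``control`` (sham surgery) and ``study`` (orthotopic)
CONTROL = "control"
STUDY = "study"


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """A parsed object violates a structural invariant."""


def _open_maybe(source, mode: str):
    """Return (file_object, needs_close) for a path or an open stream."""
    if isinstance(source, (str, Path)):
        return open(source, mode), True
    return source, False


# ---------------------------------------------------------------------------
# Spectrum
# ---------------------------------------------------------------------------


@dataclass
class Spectrum:
    """A 1D proton NMR trace with sample metadata.

    The ppm axis is stored strictly descending (the NMR display convention)
    and is expected to be referenced so the TSP singlet sits at 0.0 ppm; see
    :func:`uromet.preprocess.reference_to_tsp`.
    """

    sample_id: str
    group: str
    week: int
    ppm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.intensity.ndim != 1:
            raise ValidationError("ppm and intensity must be 1-D")
        if self.ppm.size != self.intensity.size:
            raise ValidationError(
                f"ppm ({self.ppm.size}) and intensity ({self.intensity.size}) "
                "lengths differ"
            )
        if not np.all(np.isfinite(self.ppm)) or not np.all(np.isfinite(self.intensity)):
            raise ValidationError("ppm and intensity must be finite")
        if self.ppm.size >= 2 and not np.all(np.diff(self.ppm) < 0):
            raise ValidationError("ppm axis must be strictly descending")

    @property
    def n_points(self) -> int:
        return self.ppm.size

    def shifted(self, delta: float) -> "Spectrum":
        """Return a copy with ``delta`` added to every chemical shift."""
        return replace(self, ppm=self.ppm + delta)


def read_spectrum(source, sample_id: str, group: str = CONTROL, week: int = 1) -> Spectrum:
    """Read a two-column (ppm, intensity) text file into a :class:`Spectrum`.

    Columns may be separated by whitespace or commas; lines starting with
    ``#`` and blank lines are ignored.  The ppm axis is re-sorted to
    descending order if needed, carrying intensities along.
    """
    fh, close = _open_maybe(source, "r")
    ppm, intensity = [], []
    try:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace(",", " ").split()
            if len(fields) != 2:
                raise ParseError(
                    f"line {lineno}: expected 2 columns, found {len(fields)}"
                )
            try:
                x, y = float(fields[0]), float(fields[1])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-numeric field ({exc})") from None
            if not (math.isfinite(x) and math.isfinite(y)):
                raise ParseError(f"line {lineno}: non-finite value")
            ppm.append(x)
            intensity.append(y)
    finally:
        if close:
            fh.close()
    if len(ppm) < 2:
        raise ParseError(f"need at least 2 data points, found {len(ppm)}")
    ppm_arr = np.asarray(ppm)
    int_arr = np.asarray(intensity)
    order = np.argsort(-ppm_arr, kind="stable")
    return Spectrum(sample_id=sample_id, group=group, week=week,
                    ppm=ppm_arr[order], intensity=int_arr[order])


def write_spectrum(spectrum: Spectrum, dest) -> None:
    """Write a spectrum as two-column text at full float precision."""
    fh, close = _open_maybe(dest, "w")
    try:
        fh.write(f"# sample_id={spectrum.sample_id} group={spectrum.group} "
                 f"week={spectrum.week}\n")
        for x, y in zip(spectrum.ppm, spectrum.intensity):
            fh.write(f"{float(x)!r} {float(y)!r}\n")
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# Bucket scheme
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Bucket:
    """One integration interval, ``[left, right)`` in descending ppm."""

    bucket_id: str
    left: float
    right: float

    def __post_init__(self):
        if not (self.left > self.right):
            raise ValidationError(
                f"bucket {self.bucket_id!r}: left ({self.left}) must exceed "
                f"right ({self.right}) (descending-ppm convention)"
            )

    @property
    def width(self) -> float:
        return self.left - self.right

    @property
    def center(self) -> float:
        return 0.5 * (self.left + self.right)


@dataclass
class BucketScheme:
    """An ordered set of non-overlapping buckets plus exclusion regions.

    Buckets use the closed-left / open-right ``[left, right)`` convention on
    the descending ppm axis.  No bucket may intersect an exclusion interval
    (typically water 5.00-4.50, urea 6.20-5.40 and TSP 0.20 to -0.20 ppm in
    urine work).
    """

    buckets: list[Bucket]
    exclusions: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self):
        self.buckets = list(self.buckets)
        self.exclusions = [(float(a), float(b)) for a, b in self.exclusions]
        for a, b in self.exclusions:
            if not a > b:
                raise ValidationError(
                    f"exclusion ({a}, {b}): left must exceed right"
                )
        by_left = sorted(self.buckets, key=lambda b: -b.left)
        for prev, cur in zip(by_left, by_left[1:]):
            # prev.left >= cur.left; overlap iff cur.left > prev.right
            if cur.left > prev.right:
                raise ValidationError(
                    f"buckets {prev.bucket_id!r} and {cur.bucket_id!r} overlap"
                )
        for b in self.buckets:
            for a, z in self.exclusions:
                if min(b.left, a) > max(b.right, z):
                    raise ValidationError(
                        f"bucket {b.bucket_id!r} intersects exclusion ({a}, {z})"
                    )
        ids = [b.bucket_id for b in self.buckets]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate bucket ids in scheme")

    @property
    def bucket_ids(self) -> list[str]:
        return [b.bucket_id for b in self.buckets]

    def __len__(self) -> int:
        return len(self.buckets)


def load_bucket_scheme(source) -> BucketScheme:
    """Load a :class:`BucketScheme` from YAML.

    Expected layout::

        buckets:
          - {id: B1.330, left: 1.345, right: 1.315}
          - [B1.480, 1.495, 1.465]     # list form also accepted
        exclusions:
          - [5.00, 4.50]
    """
    fh, close = _open_maybe(source, "r")
    try:
        doc = yaml.safe_load(fh)
    finally:
        if close:
            fh.close()
    if not isinstance(doc, Mapping) or "buckets" not in doc:
        raise ParseError("scheme file must be a mapping with a 'buckets' key")
    buckets = []
    for entry in doc["buckets"]:
        if isinstance(entry, Mapping):
            buckets.append(Bucket(str(entry["id"]), float(entry["left"]),
                                  float(entry["right"])))
        else:
            bid, left, right = entry
            buckets.append(Bucket(str(bid), float(left), float(right)))
    exclusions = [tuple(map(float, e)) for e in doc.get("exclusions") or []]
    return BucketScheme(buckets=buckets, exclusions=exclusions)


def save_bucket_scheme(scheme: BucketScheme, dest) -> None:
    doc = {
        "buckets": [
            {"id": b.bucket_id, "left": float(b.left), "right": float(b.right)}
            for b in scheme.buckets
        ],
        "exclusions": [[float(a), float(b)] for a, b in scheme.exclusions],
    }
    fh, close = _open_maybe(dest, "w")
    try:
        yaml.safe_dump(doc, fh, sort_keys=False)
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# Bucket table
# ---------------------------------------------------------------------------

_META_COLS = ("sample_id", "group", "week")


@dataclass
class BucketTable:
    """Samples x buckets intensity matrix with group/week metadata.

    ``values[i, k]`` is the integrated intensity of bucket ``bucket_ids[k]``
    in sample ``sample_ids[i]``.  Entries are non-negative; when
    ``normalized`` is set every row sums to 1 (total-intensity
    normalization, see :func:`uromet.preprocess.normalize_total_intensity`).
    """

    sample_ids: list[str]
    groups: list[str]
    weeks: list[int]
    bucket_ids: list[str]
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.groups = [str(g) for g in self.groups]
        self.weeks = [int(w) for w in self.weeks]
        self.bucket_ids = [str(b) for b in self.bucket_ids]
        self.values = np.asarray(self.values, dtype=float)
        n, k = len(self.sample_ids), len(self.bucket_ids)
        if self.values.shape != (n, k):
            raise ValidationError(
                f"values shape {self.values.shape} != (n_samples={n}, n_buckets={k})"
            )
        if len(self.groups) != n or len(self.weeks) != n:
            raise ValidationError("groups/weeks length must match sample_ids")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample_id in table")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("bucket values must be finite")
        if n and k:
            neg = np.argwhere(self.values < 0)
            if neg.size:
                i, j = neg[0]
                raise ValidationError(
                    f"negative value at sample {self.sample_ids[i]!r}, "
                    f"bucket {self.bucket_ids[j]!r}"
                )
            if self.normalized:
                sums = self.values.sum(axis=1)
                bad = np.argwhere(np.abs(sums - 1.0) > 1e-9)
                if bad.size:
                    i = int(bad[0][0])
                    raise ValidationError(
                        f"normalized table but row sum of sample "
                        f"{self.sample_ids[i]!r} is {sums[i]!r}"
                    )

    # -- convenience ------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_buckets(self) -> int:
        return len(self.bucket_ids)

    def group_mask(self, group: str) -> np.ndarray:
        return np.asarray([g == group for g in self.groups])

    def subset_week(self, week: int) -> "BucketTable":
        keep = [i for i, w in enumerate(self.weeks) if w == int(week)]
        return BucketTable(
            sample_ids=[self.sample_ids[i] for i in keep],
            groups=[self.groups[i] for i in keep],
            weeks=[self.weeks[i] for i in keep],
            bucket_ids=list(self.bucket_ids),
            values=self.values[keep],
            normalized=self.normalized,
        )

    def to_frame(self) -> pd.DataFrame:
        meta = pd.DataFrame({
            "sample_id": self.sample_ids,
            "group": self.groups,
            "week": self.weeks,
        })
        data = pd.DataFrame(self.values, columns=self.bucket_ids)
        return pd.concat([meta, data], axis=1)


def read_bucket_table(
    source,
    sample_col: str = "sample_id",
    group_col: str = "group",
    week_col: str = "week",
    group_labels: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> BucketTable:
    """Read a samples x buckets CSV/TSV into a :class:`BucketTable`.

    The layout is one row per sample: metadata columns then one numeric
    column per bucket.  Deposited tables whose metadata columns carry other
    names can be ingested by remapping via ``sample_col``/``group_col``/
    ``week_col``, and group spellings (e.g. ``sham``/``orthotopic``) can be
    translated to the canonical ``control``/``study`` with ``group_labels``.
    ``sep=None`` sniffs the delimiter.
    """
    fh, close = _open_maybe(source, "r")
    try:
        text = fh.read()
    finally:
        if close:
            fh.close()
    if sep is None:
        header = next((l for l in text.splitlines() if l.strip()), "")
        sep = "\t" if "\t" in header else ","
    # round_trip parsing keeps the write/read cycle bit-stable
    df = pd.read_csv(StringIO(text), sep=sep, float_precision="round_trip")
    for col in (sample_col, group_col, week_col):
        if col not in df.columns:
            raise ParseError(f"missing metadata column {col!r}; "
                             f"found {list(df.columns)!r}")
    bucket_cols = [c for c in df.columns if c not in (sample_col, group_col, week_col)]
    try:
        values = df[bucket_cols].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ParseError(f"non-numeric bucket value: {exc}") from None
    groups = [str(g) for g in df[group_col]]
    if group_labels:
        groups = [group_labels.get(g, g) for g in groups]
    return BucketTable(
        sample_ids=[str(s) for s in df[sample_col]],
        groups=groups,
        weeks=[int(w) for w in df[week_col]],
        bucket_ids=[str(c) for c in bucket_cols],
        values=values,
        normalized=False,
    )


def write_bucket_table(table: BucketTable, dest, sep: str = ",") -> None:
    """Write a bucket table as delimited text at full float precision.

    Floats are rendered with 17 significant digits so a write/read
    roundtrip is bit-stable.
    """
    fh, close = _open_maybe(dest, "w")
    try:
        table.to_frame().to_csv(fh, sep=sep, index=False, float_format="%.17g",
                                lineterminator="\n")
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# Annotation and metabolite-set library
# ---------------------------------------------------------------------------


def read_annotation(source, scheme: BucketScheme | None = None) -> dict[str, str]:
    """Read a bucket-id -> metabolite-name TSV (two columns, ``#`` comments).

    Many buckets may map to one metabolite.  If a ``scheme`` is given, every
    referenced bucket id must exist in it.
    """
    fh, close = _open_maybe(source, "r")
    mapping: dict[str, str] = {}
    try:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"line {lineno}: expected bucket_id and metabolite")
            bucket_id, metabolite = fields[0], fields[1]
            if bucket_id in mapping:
                raise ValidationError(f"line {lineno}: duplicate bucket_id {bucket_id!r}")
            mapping[bucket_id] = metabolite
    finally:
        if close:
            fh.close()
    if scheme is not None:
        known = set(scheme.bucket_ids)
        unknown = sorted(set(mapping) - known)
        if unknown:
            raise ValidationError(f"annotation references unknown buckets: {unknown}")
    return mapping


@dataclass
class MetaboliteSetLibrary:
    """Named metabolite sets (pathway stand-ins) for enrichment analysis."""

    sets: dict[str, tuple[str, list[str]]]

    def __post_init__(self):
        for set_id, (name, members) in self.sets.items():
            if not members:
                raise ValidationError(f"set {set_id!r} is empty")
            if len(set(members)) != len(members):
                raise ValidationError(f"set {set_id!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


def read_metabolite_sets(source) -> MetaboliteSetLibrary:
    """Read a set library TSV: ``set_id<TAB>set name<TAB>m1,m2,...``."""
    fh, close = _open_maybe(source, "r")
    sets: dict[str, tuple[str, list[str]]] = {}
    try:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(f"line {lineno}: expected 3 tab-separated fields")
            set_id, name, members = fields
            if set_id in sets:
                raise ValidationError(f"line {lineno}: duplicate set id {set_id!r}")
            sets[set_id] = (name, [m.strip() for m in members.split(",") if m.strip()])
    finally:
        if close:
            fh.close()
    return MetaboliteSetLibrary(sets=sets)
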