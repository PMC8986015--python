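"""Landmark dataset I/O, template definitions, and structural validation.

A *template* describes the landmarking protocol: how many fixed (anatomical)
landmarks and sliding semilandmarks a configuration carries, which ordered
curves the semilandmarks belong to, which landmark pairs define the linear
measurements (sacral width SW, corpus width CW, corpus depth CD), and named
index subsets used for regional analyses (auricular surface, first sacral
vertebra, ...).

Datasets travel as classic TPS landmark files (``LM3=``/``ID=`` records) or
as wide CSV (one specimen per row, ``x1,y1,z1,...`` columns); specimen
metadata and observer rating tables are plain CSV read through pandas.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

VALID_SEXES = ("F", "M", "U")

__all__ = [
    "CurveDefinition",
    "TemplateDefinition",
    "LandmarkConfiguration",
    "ValidationIssue",
    "ValidationReport",
    "read_tps",
    "write_tps",
    "read_coordinates_csv",
    "write_coordinates_csv",
    "read_metadata",
    "write_metadata",
    "read_ratings",
    "subset_landmarks",
    "validate_dataset",
]


@dataclass(frozen=True)
class CurveDefinition:
    """One semilandmark curve: ordered semilandmark indices plus optional
    fixed-landmark anchors at the start/end (used for tangent estimation)."""

    curve_id: str
    semilandmarks: tuple[int, ...]
    anchor_start: int | None = None
    anchor_end: int | None = None

    @property
    def chain(self) -> tuple[int, ...]:
        """Ordered point chain along the curve, anchors included."""
        pts = []
        if self.anchor_start is not None:
            pts.append(self.anchor_start)
        pts.extend(self.semilandmarks)
        if self.anchor_end is not None:
            pts.append(self.anchor_end)
        return tuple(pts)


@dataclass(frozen=True)
class TemplateDefinition:
    """Landmarking protocol: counts, curve structure, measurement endpoints.

    Indices are 0-based over the full landmark list (fixed landmarks and
    semilandmarks interleaved in digitizing order).
    """

    name: str
    n_fixed: int
    n_semi: int
    curves: tuple[CurveDefinition, ...]
    measurement_registry: dict[str, tuple[int, int]] = field(default_factory=dict)
    landmark_labels: tuple[str, ...] = ()
    subsets: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    @property
    def n_landmarks(self) -> int:
        return self.n_fixed + self.n_semi

    @property
    def semilandmark_indices(self) -> tuple[int, ...]:
        out: list[int] = []
        for c in self.curves:
            out.extend(c.semilandmarks)
        return tuple(sorted(out))

    @property
    def fixed_indices(self) -> tuple[int, ...]:
        semi = set(self.semilandmark_indices)
        return tuple(i for i in range(self.n_landmarks) if i not in semi)

    def is_semilandmark(self) -> np.ndarray:
        mask = np.zeros(self.n_landmarks, dtype=bool)
        mask[list(self.semilandmark_indices)] = True
        return mask

    def validate(self) -> None:
        k = self.n_fixed + self.n_semi
        semis: list[int] = []
        for c in self.curves:
            semis.extend(c.semilandmarks)
            for a in (c.anchor_start, c.anchor_end):
                if a is not None and not (0 <= a < k):
                    raise ValueError(
                        f"template {self.name!r}: curve {c.curve_id!r} anchor "
                        f"{a} out of range [0, {k})"
                    )
        if len(semis) != len(set(semis)):
            raise ValueError(
                f"template {self.name!r}: semilandmark index appears in more "
                "than one curve"
            )
        if len(semis) != self.n_semi:
            raise ValueError(
                f"template {self.name!r}: curves declare {len(semis)} "
                f"semilandmarks but n_semi={self.n_semi}"
            )
        if semis and (min(semis) < 0 or max(semis) >= k):
            raise ValueError(f"template {self.name!r}: semilandmark index out of range")
        for mname, (i, j) in self.measurement_registry.items():
            if not (0 <= i < k and 0 <= j < k) or i == j:
                raise ValueError(
                    f"template {self.name!r}: measurement {mname!r} endpoints "
                    f"({i}, {j}) invalid for k={k}"
                )
        if self.landmark_labels and len(self.landmark_labels) != k:
            raise ValueError(
                f"template {self.name!r}: {len(self.landmark_labels)} labels "
                f"for {k} landmarks"
            )
        for sname, idx in self.subsets.items():
            if len(idx) == 0:
                raise ValueError(f"template {self.name!r}: subset {sname!r} is empty")
            if min(idx) < 0 or max(idx) >= k:
                raise ValueError(
                    f"template {self.name!r}: subset {sname!r} index out of range"
                )

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n_fixed": self.n_fixed,
            "n_semi": self.n_semi,
            "curves": [
                {
                    "curve_id": c.curve_id,
                    "semilandmarks": list(c.semilandmarks),
                    "anchor_start": c.anchor_start,
                    "anchor_end": c.anchor_end,
                }
                for c in self.curves
            ],
            "measurement_registry": {
                k: list(v) for k, v in self.measurement_registry.items()
            },
            "landmark_labels": list(self.landmark_labels),
            "subsets": {k: list(v) for k, v in self.subsets.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TemplateDefinition":
        return cls(
            name=d["name"],
            n_fixed=int(d["n_fixed"]),
            n_semi=int(d["n_semi"]),
            curves=tuple(
                CurveDefinition(
                    curve_id=str(c["curve_id"]),
                    semilandmarks=tuple(int(i) for i in c["semilandmarks"]),
                    anchor_start=c.get("anchor_start"),
                    anchor_end=c.get("anchor_end"),
                )
                for c in d.get("curves", [])
            ),
            measurement_registry={
                k: (int(v[0]), int(v[1]))
                for k, v in d.get("measurement_registry", {}).items()
            },
            landmark_labels=tuple(d.get("landmark_labels", [])),
            subsets={
                k: tuple(int(i) for i in v) for k, v in d.get("subsets", {}).items()
            },
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TemplateDefinition":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class LandmarkConfiguration:
    """One specimen's k x 3 landmark coordinates (mm) plus its template."""

    specimen_id: str
    coordinates: np.ndarray
    template: TemplateDefinition

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError(
                f"specimen {self.specimen_id!r}: coordinates must be k x 3, "
                f"got shape {self.coordinates.shape}"
            )
        if self.coordinates.shape[0] != self.template.n_landmarks:
            raise ValueError(
                f"specimen {self.specimen_id!r}: {self.coordinates.shape[0]} "
                f"landmarks but template {self.template.name!r} declares "
                f"{self.template.n_landmarks}"
            )

    @property
    def k(self) -> int:
        return self.coordinates.shape[0]

    def copy(self) -> "LandmarkConfiguration":
        return LandmarkConfiguration(
            self.specimen_id, self.coordinates.copy(), self.template
        )


# ---------------------------------------------------------------------------
# TPS landmark-file format
# ---------------------------------------------------------------------------

def read_tps(path, template: TemplateDefinition) -> list[LandmarkConfiguration]:
    """Read a classic TPS landmark file (``LM3=`` records) into configurations.

    Records must declare their landmark count with ``LM3=`` (3D) and may carry
    an ``ID=`` line; IDs default to ``specimen_<i>`` in file order. ``SCALE=``
    lines are ignored. The landmark count of every record is checked against
    the template.
    """
    configs: list[LandmarkConfiguration] = []
    count = None
    coords: list[list[float]] = []
    spec_id = None
    record_line = 0

    def flush(lineno):
        nonlocal count, coords, spec_id
        if count is None:
            return
        if len(coords) != count:
            raise ValueError(
                f"TPS parse error near line {lineno}: record declared "
                f"LM3={count} but has {len(coords)} coordinate lines"
            )
        sid = spec_id if spec_id is not None else f"specimen_{len(configs)}"
        arr = np.array(coords, dtype=float)
        if arr.shape[0] != template.n_landmarks:
            raise ValueError(
                f"specimen {sid!r} (record starting line {record_line}): "
                f"{arr.shape[0]} landmarks, template expects "
                f"{template.n_landmarks}"
            )
        configs.append(LandmarkConfiguration(sid, arr, template))
        count, coords, spec_id = None, [], None

    lineno = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM3=") or upper.startswith("LM="):
                flush(lineno)
                record_line = lineno
                try:
                    count = int(line.split("=", 1)[1])
                except ValueError as exc:
                    raise ValueError(
                        f"TPS parse error at line {lineno}: bad count {line!r}"
                    ) from exc
                if upper.startswith("LM=") and count > 0:
                    raise ValueError(
                        f"TPS parse error at line {lineno}: 2D record (LM=) "
                        "not supported, expected LM3="
                    )
            elif upper.startswith("ID="):
                spec_id = line.split("=", 1)[1].strip()
            elif upper.startswith("SCALE=") or upper.startswith("IMAGE="):
                continue
            else:
                if count is None:
                    raise ValueError(
                        f"TPS parse error at line {lineno}: coordinate line "
                        "outside a record"
                    )
                parts = line.split()
                if len(parts) != 3:
                    raise ValueError(
                        f"TPS parse error at line {lineno}: expected 3 "
                        f"coordinates, got {len(parts)}"
                    )
                try:
                    coords.append([float(p) for p in parts])
                except ValueError as exc:
                    raise ValueError(
                        f"TPS parse error at line {lineno}: non-numeric "
                        f"coordinate in {line!r}"
                    ) from exc
    flush(lineno)
    return configs


def write_tps(configs: list[LandmarkConfiguration], path) -> None:
    """Write configurations as a TPS landmark file (round-trip safe)."""
    if not configs:
        raise ValueError("write_tps: empty configuration list")
    tpl = configs[0].template
    for c in configs:
        if c.template is not tpl and c.template != tpl:
            raise ValueError(
                "write_tps: heterogeneous templates "
                f"({c.template.name!r} vs {tpl.name!r})"
            )
    buf = io.StringIO()
    for c in configs:
        buf.write(f"LM3={c.k}\n")
        for x, y, z in c.coordinates:
            buf.write(f"{x:.17g} {y:.17g} {z:.17g}\n")
        buf.write(f"ID={c.specimen_id}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# Wide CSV coordinates and metadata
# ---------------------------------------------------------------------------

def write_coordinates_csv(configs: list[LandmarkConfiguration], path) -> None:
    """One specimen per row: specimen_id, x1, y1, z1, x2, ..."""
    if not configs:
        raise ValueError("write_coordinates_csv: empty configuration list")
    k = configs[0].k
    cols = ["specimen_id"] + [
        f"{ax}{i + 1}" for i in range(k) for ax in ("x", "y", "z")
    ]
    rows = [
        [c.specimen_id] + list(c.coordinates.reshape(-1)) for c in configs
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_coordinates_csv(path, template: TemplateDefinition) -> list[LandmarkConfiguration]:
    df = pd.read_csv(path)
    k = template.n_landmarks
    coord_cols = [f"{ax}{i + 1}" for i in range(k) for ax in ("x", "y", "z")]
    missing = [c for c in coord_cols if c not in df.columns]
    if missing:
        raise ValueError(
            f"coordinate CSV missing columns (first few): {missing[:6]}"
        )
    return [
        LandmarkConfiguration(
            str(row["specimen_id"]),
            np.asarray(row[coord_cols], dtype=float).reshape(k, 3),
            template,
        )
        for _, row in df.iterrows()
    ]


def read_metadata(path) -> pd.DataFrame:
    """Specimen metadata CSV: specimen_id, sex (F/M/U), group[, collection]."""
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"specimen_id", "sex", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata CSV missing columns: {sorted(missing)}")
    bad = df.loc[~df["sex"].isin(VALID_SEXES), "specimen_id"].tolist()
    if bad:
        raise ValueError(f"metadata: invalid sex codes for specimens {bad}")
    if df["specimen_id"].duplicated().any():
        dup = df.loc[df["specimen_id"].duplicated(), "specimen_id"].tolist()
        raise ValueError(f"metadata: duplicate specimen ids {dup}")
    return df


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, index=False)


def read_ratings(path) -> pd.DataFrame:
    """Observer rating CSV: specimen_id, observer, round (1/2), rating (F/M)
    and optionally a truth column (true sex per specimen)."""
    df = pd.read_csv(path, dtype={"specimen_id": str, "observer": str})
    required = {"specimen_id", "observer", "round", "rating"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"rating CSV missing columns: {sorted(missing)}")
    if df.duplicated(subset=["specimen_id", "observer", "round"]).any():
        raise ValueError("rating table: duplicate (specimen, observer, round) rows")
    if not df["rating"].isin(("F", "M")).all():
        raise ValueError("rating table: ratings must be F or M")
    return df


# ---------------------------------------------------------------------------
# Subsetting
# ---------------------------------------------------------------------------

def subset_landmarks(
    configs: list[LandmarkConfiguration],
    template: TemplateDefinition,
    subset_name: str,
) -> tuple[list[LandmarkConfiguration], TemplateDefinition]:
    """Restrict a dataset to a named landmark subset of the template.

    Curve memberships are re-indexed. A surviving semilandmark whose chain
    neighbors (in the original curve) are *both* removed loses its sliding
    status and becomes a fixed landmark — a tangent cannot be estimated for
    it. Curves left without semilandmarks are dropped; measurement-registry
    entries survive only if both endpoints survive.
    """
    if subset_name not in template.subsets:
        raise KeyError(
            f"unknown subset {subset_name!r}; available: "
            f"{sorted(template.subsets)}"
        )
    keep = sorted(set(template.subsets[subset_name]))
    keep_set = set(keep)
    new_index = {old: new for new, old in enumerate(keep)}

    new_curves: list[CurveDefinition] = []
    demoted: set[int] = set()
    surviving_semis: set[int] = set()
    for c in template.curves:
        chain = c.chain
        pos = {p: i for i, p in enumerate(chain)}
        kept_semis = [s for s in c.semilandmarks if s in keep_set]
        chain_kept = [p for p in chain if p in keep_set]
        final_semis = []
        for s in kept_semis:
            i = pos[s]
            prev_ok = i - 1 >= 0 and chain[i - 1] in keep_set
            next_ok = i + 1 < len(chain) and chain[i + 1] in keep_set
            if not prev_ok and not next_ok:
                demoted.add(s)  # isolated on its curve: no tangent
            else:
                final_semis.append(s)
        surviving_semis.update(final_semis)
        if not final_semis:
            continue
        a0 = c.anchor_start if c.anchor_start in keep_set else None
        a1 = c.anchor_end if c.anchor_end in keep_set else None
        new_curves.append(
            CurveDefinition(
                curve_id=c.curve_id,
                semilandmarks=tuple(new_index[s] for s in final_semis),
                anchor_start=None if a0 is None else new_index[a0],
                anchor_end=None if a1 is None else new_index[a1],
            )
        )
        del chain_kept

    n_semi = len(surviving_semis)
    n_fixed = len(keep) - n_semi
    new_registry = {
        m: (new_index[i], new_index[j])
        for m, (i, j) in template.measurement_registry.items()
        if i in keep_set and j in keep_set
    }
    labels = (
        tuple(template.landmark_labels[i] for i in keep)
        if template.landmark_labels
        else ()
    )
    new_subsets = {}
    for sname, idx in template.subsets.items():
        inter = tuple(new_index[i] for i in idx if i in keep_set)
        if inter:
            new_subsets[sname] = inter
    new_template = TemplateDefinition(
        name=f"{template.name}:{subset_name}",
        n_fixed=n_fixed,
        n_semi=n_semi,
        curves=tuple(new_curves),
        measurement_registry=new_registry,
        landmark_labels=labels,
        subsets=new_subsets,
    )
    new_configs = [
        LandmarkConfiguration(c.specimen_id, c.coordinates[keep], new_template)
        for c in configs
    ]
    return new_configs, new_template


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationIssue:
    specimen_id: str
    code: str
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue]

    @property
    def ok(self) -> bool:
        return not self.issues

    def by_code(self, code: str) -> list[ValidationIssue]:
        return [i for i in self.issues if i.code == code]


def validate_dataset(
    configs: list[LandmarkConfiguration],
    meta: pd.DataFrame | None = None,
    coincidence_tol: float = 1e-9,
) -> ValidationReport:
    """Structural validation (report-only, never mutates or drops).

    Flags non-finite coordinates, exactly coincident landmark pairs,
    duplicated specimen ids, specimens missing from the metadata, and
    specimens of unknown sex (``U``) which stay in the sample but are
    excluded from classification-accuracy analyses.
    """
    issues: list[ValidationIssue] = []
    seen: set[str] = set()
    for c in configs:
        if c.specimen_id in seen:
            issues.append(
                ValidationIssue(c.specimen_id, "duplicate_id", "specimen id not unique")
            )
        seen.add(c.specimen_id)
        if not np.all(np.isfinite(c.coordinates)):
            issues.append(
                ValidationIssue(
                    c.specimen_id, "non_finite", "non-finite coordinate present"
                )
            )
            continue
        d = c.coordinates[:, None, :] - c.coordinates[None, :, :]
        dist = np.sqrt((d ** 2).sum(-1))
        iu = np.triu_indices(c.k, 1)
        if (dist[iu] < coincidence_tol).any():
            issues.append(
                ValidationIssue(
                    c.specimen_id,
                    "coincident_landmarks",
                    f"landmark pair closer than {coincidence_tol} mm",
                )
            )
    if meta is not None:
        meta_ids = set(meta["specimen_id"].astype(str))
        for c in configs:
            if c.specimen_id not in meta_ids:
                issues.append(
                    ValidationIssue(
                        c.specimen_id, "missing_metadata", "no metadata row"
                    )
                )
        config_ids = {c.specimen_id for c in configs}
        for _, row in meta.iterrows():
            sid = str(row["specimen_id"])
            if row["sex"] == "U" and sid in config_ids:
                issues.append(
                    ValidationIssue(
                        sid,
                        "excluded_from_classification",
                        "sex unknown: kept in sample, excluded from "
                        "classification accuracy",
                    )
                )
    return ValidationReport(issues)
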