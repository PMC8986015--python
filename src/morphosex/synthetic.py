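"""Synthetic sacrum-like landmark populations with known ground truth.

The generator emulates the statistical structure a sacral sex-dimorphism
analysis assumes, without claiming biomechanical realism:

* a deterministic parametric "sacrum-like" reference: a tapering, sagittally
  curved body with bilateral alae flanges, 44 fixed landmarks and 56
  semilandmarks on 7 smooth curves, bilaterally symmetric, with registered
  SW/CW/CD measurement endpoints at known default distances;
* interpretable deformation modes built from the template geometry (alae
  widening, corpus scaling, elongation, promontory protrusion, sagittal
  curvature, sacral-canal expansion), each orthogonal to the similarity
  transformations of the reference and mutually orthonormal, so that sex,
  allometric and group mean effects have exactly computable variance shares;
* per-specimen structure: shape = reference + sex offset + group offset +
  allometric field * (lnCS - mean lnCS) + isotropic landmark noise (+
  tangential jitter of the semilandmarks to exercise sliding), then scaled
  to a lognormally drawn centroid size.

Everything is reproducible from a single integer seed, and the exported
ground truth carries the noise-free configurations and true parameters for
parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landmark_io import CurveDefinition, LandmarkConfiguration, TemplateDefinition

__all__ = [
    "make_template",
    "default_template",
    "shape_modes",
    "similarity_basis",
    "PopulationSpec",
    "GroundTruth",
    "default_population_spec",
    "simulate_dataset",
    "simulate_measurements",
    "DEFAULT_MEASUREMENT_PROFILE",
]

# default reference dimensions (mm), between the published female and male
# complete-sample means so both sexes are small perturbations of the reference
_SW, _CW, _CD, _H = 113.0, 48.0, 30.0, 108.0


def _arc(p0, p1, bulge, t):
    """Point(s) on a smooth arc from p0 to p1 with a sinusoidal bulge."""
    p0, p1, bulge = (np.asarray(v, float) for v in (p0, p1, bulge))
    t = np.atleast_1d(np.asarray(t, float))[:, None]
    return p0 + t * (p1 - p0) + np.sin(np.pi * t) * bulge


def make_template(style: str = "sacrum-like", seed: int = 0):
    """Deterministic sacrum-like template and reference configuration.

    Returns ``(template, reference)`` with 44 fixed landmarks, 56
    semilandmarks on 7 curves, registered SW/CW/CD endpoints (defaults
    113 > 48 > 30 mm) and named subsets (fixed_only, auricular, corpus, S1,
    S1S2). ``seed`` is accepted for interface symmetry but the geometry is
    fully deterministic.

    Axes: x mediolateral (right +), y anteroposterior (anterior +),
    z craniocaudal (cranial 0, caudal negative). Units mm.
    """
    if style != "sacrum-like":
        raise ValueError(f"unknown template style {style!r}")
    del seed  # geometry is deterministic

    labels: list[str] = []
    pts: list[np.ndarray] = []

    def add(label, p):
        labels.append(label)
        pts.append(np.asarray(p, float))
        return len(pts) - 1

    # --- fixed landmarks (44) -----------------------------------------
    # corpus superior rim: 8 points on an ellipse at z = 0
    rim_names = [
        "corpus_lat_R", "corpus_antlat_R", "corpus_ant", "corpus_antlat_L",
        "corpus_lat_L", "corpus_postlat_L", "corpus_post", "corpus_postlat_R",
    ]
    rim_idx = []
    for name, ang in zip(rim_names, np.deg2rad(np.arange(0, 360, 45))):
        rim_idx.append(
            add(name, (_CW / 2 * np.cos(ang), _CD / 2 * np.sin(ang), 0.0))
        )
    # alae superior surface: 4 points per side, tip = SW endpoint
    ala_idx = {"R": [], "L": []}
    for side, sgn in (("R", 1.0), ("L", -1.0)):
        for j, f in enumerate((0.25, 0.5, 0.75, 1.0), start=1):
            x = sgn * (_CW / 2 + f * (_SW - _CW) / 2)
            ala_idx[side].append(add(f"ala_{j}_{side}", (x, 3 - 8 * f, -1 - 3 * f)))
    # anterior midline (sagittal-curvature) points
    ant_idx = []
    for i in range(1, 7):
        u = i / 7
        ant_idx.append(
            add(f"ant_mid_{i}", (0.0, 14 + 12 * np.sin(np.pi * u) - 10 * u, -u * _H))
        )
    # dorsal midline points
    dors_idx = []
    for i in range(1, 7):
        u = i / 7
        dors_idx.append(
            add(f"dors_mid_{i}", (0.0, -25 - 8 * np.sin(np.pi * u) + 6 * u, -u * _H))
        )
    # auricular surface corners (patch per side)
    auric_idx = {"R": [], "L": []}
    for side, sgn in (("R", 1.0), ("L", -1.0)):
        xa = sgn * (_SW / 2 - 12)
        for name, y, z in (
            ("asup", -2, -14), ("ainf", -2, -34), ("psup", -12, -14), ("pinf", -12, -34),
        ):
            auric_idx[side].append(add(f"auric_{name}_{side}", (xa, y, z)))
    # superior articular processes
    art_idx = {
        "R": add("artproc_R", (12.0, -22.0, 4.0)),
        "L": add("artproc_L", (-12.0, -22.0, 4.0)),
    }
    # lateral margin
    lat_idx = {"R": [], "L": []}
    for side, sgn in (("R", 1.0), ("L", -1.0)):
        lat_idx[side].append(add(f"lat_marg_1_{side}", (sgn * (_SW / 2 - 8), -6.0, -28.0)))
        lat_idx[side].append(add(f"lat_marg_2_{side}", (sgn * (_SW / 2 - 22), -4.0, -55.0)))
    # apex
    apex_ant = add("apex_ant", (0.0, 6.0, -108.0))
    apex_post = add("apex_post", (0.0, -16.0, -108.0))

    n_fixed = len(pts)
    assert n_fixed == 44, n_fixed

    # --- semilandmark curves (7 x 8 = 56) -----------------------------
    t8 = (np.arange(1, 9)) / 9.0
    curves: list[CurveDefinition] = []

    def add_curve(curve_id, anchor_a, anchor_b, bulge, mirror_of=None):
        if mirror_of is None:
            arc = _arc(pts[anchor_a], pts[anchor_b], bulge, t8)
        else:
            arc = np.array(mirror_of) * np.array([-1.0, 1.0, 1.0])
        semi_ids = [
            add(f"{curve_id}_s{j + 1}", arc[j]) for j in range(len(arc))
        ]
        curves.append(
            CurveDefinition(
                curve_id=curve_id,
                semilandmarks=tuple(semi_ids),
                anchor_start=anchor_a,
                anchor_end=anchor_b,
            )
        )
        return arc

    # superior articular surface curves (between articular process and the
    # posterior corpus rim)
    arc_sa_r = add_curve("sup_artic_R", art_idx["R"], rim_idx[6], (2.0, -3.0, 3.0))
    add_curve("sup_artic_L", art_idx["L"], rim_idx[6],
              (0, 0, 0), mirror_of=arc_sa_r)
    # dorsal (median) crest: stays on the midsagittal plane
    add_curve("dorsal_crest", dors_idx[0], dors_idx[-1], (0.0, -5.0, 0.0))
    # lateral crests: ala tip down to the apex region
    arc_lc_r = add_curve("lat_crest_R", ala_idx["R"][3], apex_post, (6.0, -6.0, 0.0))
    add_curve("lat_crest_L", ala_idx["L"][3], apex_post, (0, 0, 0), mirror_of=arc_lc_r)
    # auricular surface outlines
    arc_au_r = add_curve("auric_R", auric_idx["R"][0], auric_idx["R"][3], (-4.0, 2.0, 2.0))
    add_curve("auric_L", auric_idx["L"][0], auric_idx["L"][3], (0, 0, 0), mirror_of=arc_au_r)

    reference = np.array(pts)
    n_semi = len(pts) - n_fixed
    assert n_semi == 56, n_semi

    # --- subsets -------------------------------------------------------
    sup_artic_semis = [i for c in curves if c.curve_id.startswith("sup_artic")
                       for i in c.semilandmarks]
    auric_semis = [i for c in curves if c.curve_id.startswith("auric")
                   for i in c.semilandmarks]
    subsets = {
        "fixed_only": tuple(range(n_fixed)),
        "corpus": tuple(sorted(rim_idx + list(art_idx.values()) + sup_artic_semis)),
        "auricular": tuple(sorted(auric_idx["R"] + auric_idx["L"] + auric_semis)),
        "S1": tuple(sorted(np.nonzero(reference[:, 2] >= -22.0)[0].tolist())),
        "S1S2": tuple(sorted(np.nonzero(reference[:, 2] >= -45.0)[0].tolist())),
    }

    template = TemplateDefinition(
        name="sacrum-like",
        n_fixed=n_fixed,
        n_semi=n_semi,
        curves=tuple(curves),
        measurement_registry={
            "SW": (ala_idx["R"][3], ala_idx["L"][3]),
            "CW": (rim_idx[0], rim_idx[4]),
            "CD": (rim_idx[2], rim_idx[6]),
        },
        landmark_labels=tuple(labels),
        subsets=subsets,
    )
    return template, reference


_DEFAULT_CACHE: dict = {}


def default_template():
    """Cached default sacrum-like template and reference."""
    if "tpl" not in _DEFAULT_CACHE:
        _DEFAULT_CACHE["tpl"] = make_template()
    return _DEFAULT_CACHE["tpl"]


# ---------------------------------------------------------------------------
# Deformation modes
# ---------------------------------------------------------------------------

def similarity_basis(reference: np.ndarray) -> np.ndarray:
    """Orthonormal basis (3k x 7) of the similarity transformations of a
    centered reference: 3 translations, 3 infinitesimal rotations, 1 scaling."""
    ref = np.asarray(reference, float)
    ref = ref - ref.mean(axis=0)
    k = ref.shape[0]
    cols = []
    for ax in range(3):
        v = np.zeros((k, 3))
        v[:, ax] = 1.0
        cols.append(v.ravel())
    gens = [
        np.array([[0, -1, 0], [1, 0, 0], [0, 0, 0]], float),
        np.array([[0, 0, 1], [0, 0, 0], [-1, 0, 0]], float),
        np.array([[0, 0, 0], [0, 0, -1], [0, 1, 0]], float),
    ]
    for g in gens:
        cols.append((ref @ g.T).ravel())
    cols.append(ref.ravel())
    b = np.column_stack(cols)
    q, _ = np.linalg.qr(b)
    return q


def _project_out_similarity(fields: np.ndarray, reference: np.ndarray) -> np.ndarray:
    q = similarity_basis(reference)
    flat = fields.reshape(fields.shape[0], -1)
    flat = flat - (flat @ q) @ q.T
    return flat.reshape(fields.shape)


def shape_modes(template: TemplateDefinition, reference: np.ndarray) -> dict[str, np.ndarray]:
    """Interpretable, mutually orthonormal shape deformation modes.

    Each mode is a k x 3 field with unit Frobenius norm, orthogonal to the
    similarity transformations of the (unit-size, centered) reference and to
    the other modes. Keys:

    ``alae_width``   mediolateral expansion of the alae relative to the corpus
    ``corpus_scale`` in-plane scaling of the corpus superior rim
    ``elongation``   craniocaudal stretch at fixed width (length/width mode)
    ``promontory``   anterior protrusion of the promontory region
    ``sag_curvature`` sagittal (y) bending along the craniocaudal axis
    ``canal``        posterior displacement of the dorsal/articular region
                     (sacral-canal expansion)
    """
    ref = np.asarray(reference, float)
    ref = ref - ref.mean(axis=0)
    cs = np.sqrt((ref ** 2).sum())
    ref = ref / cs  # unit-size shape domain
    k = ref.shape[0]
    lab = template.landmark_labels
    x, y, z = ref[:, 0], ref[:, 1], ref[:, 2]
    cw_half = _CW / 2 / cs

    raw = {}
    f = np.zeros((k, 3))
    w = np.clip(np.abs(x) - cw_half, 0.0, None)
    f[:, 0] = np.sign(x) * w
    raw["alae_width"] = f

    f = np.zeros((k, 3))
    corpus = np.array([l.startswith("corpus_") for l in lab])
    f[corpus, 0] = x[corpus]
    f[corpus, 1] = y[corpus]
    raw["corpus_scale"] = f

    f = np.zeros((k, 3))
    f[:, 2] = z - z.mean()
    f[:, 0] = -0.5 * x
    raw["elongation"] = f

    f = np.zeros((k, 3))
    prom = np.array(
        [l in ("corpus_ant", "corpus_antlat_R", "corpus_antlat_L", "ant_mid_1")
         for l in lab]
    )
    f[prom, 1] = 1.0
    raw["promontory"] = f

    f = np.zeros((k, 3))
    depth = np.clip(-z, 0.0, None)
    f[:, 1] = np.sin(np.pi * depth / depth.max())
    raw["sag_curvature"] = f

    f = np.zeros((k, 3))
    dorsal = np.array(
        [l.startswith(("dors_mid", "artproc", "sup_artic", "dorsal_crest"))
         for l in lab]
    )
    f[dorsal, 1] = -1.0
    raw["canal"] = f

    names = list(raw)
    stack = np.stack([raw[n] for n in names])
    stack = _project_out_similarity(stack, ref)
    # Gram-Schmidt across modes (order as listed above)
    flat = stack.reshape(len(names), -1)
    q, r = np.linalg.qr(flat.T)
    signs = np.sign(np.diag(r))
    q = q * signs
    return {n: q[:, i].reshape(k, 3) for i, n in enumerate(names)}


# ---------------------------------------------------------------------------
# Population specification and simulation
# ---------------------------------------------------------------------------

@dataclass
class PopulationSpec:
    """Stated generative world for a landmark population.

    ``sex_field`` is a unit-norm k x 3 field in the unit-size shape domain;
    male shapes get +d_shape/2 of it, female shapes -d_shape/2 (so the
    male-female mean difference equals d_shape * sex_field). The allometric
    field enters per unit of (lnCS - population mean lnCS). Group offsets
    are absolute fields per geographic group. Noise SDs are fractions of
    centroid size (the unit-shape scale).
    """

    template: TemplateDefinition
    reference: np.ndarray
    cells: dict  # (sex, group) -> n
    sex_field: np.ndarray
    d_shape: float
    allometric_field: np.ndarray
    allometry_scale: float
    group_offsets: dict
    size_log_mean: dict  # (sex, group) -> mean of lnCS
    size_log_sd: float
    landmark_noise_sd: float = 0.005
    semilandmark_tangential_jitter_sd: float = 0.005
    measurement_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not self.cells or all(n == 0 for n in self.cells.values()):
            raise ValueError("population spec has no specimens")
        if any(n < 0 for n in self.cells.values()):
            raise ValueError("negative cell size")
        for name in ("landmark_noise_sd", "semilandmark_tangential_jitter_sd",
                     "measurement_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_total(self) -> int:
        return sum(self.cells.values())

    def expected_mean_lncs(self) -> float:
        n = self.n_total
        return sum(
            self.cells[c] * self.size_log_mean[c] for c in self.cells
        ) / n


@dataclass
class GroundTruth:
    """Per-specimen truth aligned 1:1 with the generated configurations."""

    frame: pd.DataFrame  # specimen_id, sex, group, lncs
    true_configurations: np.ndarray  # noise-free, mm
    spec: PopulationSpec


# Table-2-like composition of known-sex specimens per geographic group
_DEFAULT_CELLS = {
    ("F", "European"): 51, ("M", "European"): 52,
    ("F", "West African"): 5, ("M", "West African"): 11,
    ("F", "Khoesan-Pygmy"): 9, ("M", "Khoesan-Pygmy"): 12,
    ("F", "South-East Asian"): 2, ("M", "South-East Asian"): 7,
    ("F", "Native American"): 4, ("M", "Native American"): 2,
}

# relative body-size offsets (on lnCS) per group; small-bodied groups smaller
_DEFAULT_GROUP_LNCS = {
    "European": 0.00,
    "West African": -0.03,
    "Khoesan-Pygmy": -0.12,
    "South-East Asian": -0.05,
    "Native American": -0.02,
}

# published variance shares emulated by the defaults: sex 2.2%, size (lnCS)
# 1.7%, geographic origin 3.7% of total shape variance
_SHARE_SEX, _SHARE_SIZE, _SHARE_GROUP = 0.022, 0.017, 0.037


def default_population_spec(seed: int, cells: dict | None = None) -> PopulationSpec:
    """Default stated world: five geographic groups with the study's
    known-sex cell sizes, effect magnitudes derived once from the published
    variance shares, sexes differing in size by the published sacral-width
    ratio, and 0.5% digitizing noise."""
    template, reference = default_template()
    modes = shape_modes(template, reference)
    cells = dict(cells) if cells is not None else dict(_DEFAULT_CELLS)

    # male-female direction: broader corpus, narrower alae, relative
    # elongation, protruding promontory
    sex_field = (
        0.45 * modes["corpus_scale"]
        - 0.45 * modes["alae_width"]
        + 0.55 * modes["elongation"]
        + 0.30 * modes["promontory"]
        + 0.45 * modes["sag_curvature"]
    )
    sex_field /= np.linalg.norm(sex_field)
    allometric_field = modes["sag_curvature"]

    ref_c = reference - reference.mean(axis=0)
    cs_ref = float(np.sqrt((ref_c ** 2).sum()))
    log_sd = 0.05
    sex_size_ratio = np.log(113.7 / 112.3)  # male/female sacral width ratio
    size_log_mean = {}
    for (sex, group) in cells:
        mu = np.log(cs_ref) + _DEFAULT_GROUP_LNCS[group]
        if sex == "M":
            mu += sex_size_ratio
        size_log_mean[(sex, group)] = mu

    n = sum(cells.values())
    noise_sd, jitter_sd = 0.005, 0.005
    noise_var = 3 * template.n_landmarks * noise_sd ** 2 \
        + template.n_semi * jitter_sd ** 2
    total_var = noise_var / (1.0 - _SHARE_SEX - _SHARE_SIZE - _SHARE_GROUP)

    p_m = sum(v for (s, _), v in cells.items() if s == "M") / n
    d_shape = float(np.sqrt(_SHARE_SEX * total_var / (p_m * (1 - p_m))))

    # lnCS variance: within-cell + between-cell
    mean_lncs = sum(cells[c] * size_log_mean[c] for c in cells) / n
    between = sum(
        cells[c] * (size_log_mean[c] - mean_lncs) ** 2 for c in cells
    ) / n
    var_lncs = log_sd ** 2 + between
    allometry_scale = float(np.sqrt(_SHARE_SIZE * total_var / var_lncs))

    # raw group pattern: curvature strongest in Europeans, flattest and with
    # the widest sacral canal in the small-bodied groups
    raw_group = {
        "European": 1.0 * modes["sag_curvature"] + 0.0 * modes["canal"],
        "West African": -0.5 * modes["sag_curvature"] + 0.2 * modes["canal"],
        "Khoesan-Pygmy": -1.0 * modes["sag_curvature"] + 0.8 * modes["canal"],
        "South-East Asian": -0.3 * modes["sag_curvature"] + 0.2 * modes["canal"],
        "Native American": -0.8 * modes["sag_curvature"] + 0.1 * modes["canal"],
    }
    groups = {g for (_, g) in cells}
    w = {g: sum(v for (s, gg), v in cells.items() if gg == g) / n for g in groups}
    flat = {g: raw_group[g].reshape(-1) for g in groups}
    gbar = sum(w[g] * flat[g] for g in groups)
    raw_var = sum(w[g] * ((flat[g] - gbar) ** 2).sum() for g in groups)
    scale = np.sqrt(_SHARE_GROUP * total_var / raw_var) if raw_var > 0 else 0.0
    group_offsets = {g: scale * raw_group[g] for g in groups}

    return PopulationSpec(
        template=template,
        reference=reference,
        cells=cells,
        sex_field=sex_field,
        d_shape=d_shape,
        allometric_field=allometric_field,
        allometry_scale=allometry_scale,
        group_offsets=group_offsets,
        size_log_mean=size_log_mean,
        size_log_sd=log_sd,
        landmark_noise_sd=noise_sd,
        semilandmark_tangential_jitter_sd=jitter_sd,
        seed=seed,
    )


def _reference_tangents(template: TemplateDefinition, reference: np.ndarray):
    from .semilandmarks import curve_tangents

    return curve_tangents(np.asarray(reference, float), template)


def simulate_dataset(spec: PopulationSpec):
    """Draw a landmark population from a PopulationSpec.

    Returns ``(configs, meta, truth)``: landmark configurations in mm (raw
    frame, no random rotation applied — superimposition is exercised by the
    analysis pipeline, not faked here), a metadata table, and the ground
    truth with noise-free configurations.
    """
    rng = np.random.default_rng(spec.seed)
    ref = np.asarray(spec.reference, float)
    ref_c = ref - ref.mean(axis=0)
    cs_ref = float(np.sqrt((ref_c ** 2).sum()))
    ref_unit = ref_c / cs_ref
    k = ref.shape[0]
    mean_lncs = spec.expected_mean_lncs()
    semi_idx, semi_tan = _reference_tangents(spec.template, ref_unit)

    configs: list[LandmarkConfiguration] = []
    meta_rows = []
    truth_rows = []
    true_configs = []
    counter = 0
    for (sex, group) in sorted(spec.cells):
        n_cell = spec.cells[(sex, group)]
        sign = 0.5 if sex == "M" else -0.5
        for _ in range(n_cell):
            sid = f"sp{counter:04d}"
            counter += 1
            lncs = rng.normal(spec.size_log_mean[(sex, group)], spec.size_log_sd)
            shape_true = (
                ref_unit
                + sign * spec.d_shape * spec.sex_field
                + spec.group_offsets.get(group, 0.0)
                + spec.allometry_scale * (lncs - mean_lncs) * spec.allometric_field
            )
            shape = shape_true + rng.normal(0.0, spec.landmark_noise_sd, (k, 3))
            if spec.semilandmark_tangential_jitter_sd > 0 and semi_idx.size:
                s = rng.normal(0.0, spec.semilandmark_tangential_jitter_sd,
                               semi_idx.size)
                shape[semi_idx] += s[:, None] * semi_tan
            cs = float(np.exp(lncs))
            configs.append(
                LandmarkConfiguration(sid, shape * cs, spec.template)
            )
            true_configs.append(shape_true * cs)
            meta_rows.append(
                {"specimen_id": sid, "sex": sex, "group": group,
                 "collection": "synthetic"}
            )
            truth_rows.append(
                {"specimen_id": sid, "sex": sex, "group": group, "lncs": lncs}
            )
    meta = pd.DataFrame(meta_rows)
    truth = GroundTruth(
        frame=pd.DataFrame(truth_rows),
        true_configurations=np.stack(true_configs),
        spec=spec,
    )
    return configs, meta, truth


# ---------------------------------------------------------------------------
# Linear-measurement simulation
# ---------------------------------------------------------------------------

# per-sex means and SDs (mm) of SW/CW/CD mirroring the published
# complete-sample univariate table, with the published correlations
DEFAULT_MEASUREMENT_PROFILE = {
    "mean": {"F": np.array([112.3, 46.1, 28.3]), "M": np.array([113.7, 51.5, 31.8])},
    "sd": {"F": np.array([10.0, 4.3, 2.9]), "M": np.array([10.8, 4.7, 2.8])},
    "correlation": np.array(
        [[1.00, 0.42, 0.30],
         [0.42, 1.00, 0.70],
         [0.30, 0.70, 1.00]]
    ),
}


def simulate_measurements(
    n_f: int,
    n_m: int,
    effect_profile: dict | None = None,
    seed: int | None = None,
    measurement_noise_sd: float = 0.0,
):
    """Per-sex correlated Gaussian SW/CW/CD samples.

    Returns ``(table, truth)``: a DataFrame (specimen_id, sex, SW, CW, CD)
    and the profile actually used. Indices are computed downstream (via
    :mod:`morphosex.osteometrics`), not generated. Optional
    ``measurement_noise_sd`` adds independent caliper/digitizing error (mm).
    """
    profile = effect_profile or DEFAULT_MEASUREMENT_PROFILE
    corr = np.asarray(profile["correlation"], float)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation matrix is not positive definite") from exc
    rng = np.random.default_rng(seed)
    rows = []
    counter = 0
    for sex, n in (("F", n_f), ("M", n_m)):
        mean = np.asarray(profile["mean"][sex], float)
        sd = np.asarray(profile["sd"][sex], float)
        z = rng.standard_normal((n, 3)) @ chol.T
        vals = mean + z * sd
        if measurement_noise_sd > 0:
            vals = vals + rng.normal(0.0, measurement_noise_sd, vals.shape)
        for v in vals:
            rows.append(
                {"specimen_id": f"m{counter:04d}", "sex": sex,
                 "SW": v[0], "CW": v[1], "CD": v[2]}
            )
            counter += 1
    table = pd.DataFrame(rows)
    return table, {"profile": profile, "seed": seed}
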