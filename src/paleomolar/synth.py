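"""Seeded synthetic-data generators.

Every analysis stage in this package can be exercised without any external
download: each generator here forward-models inputs with the statistical
structure the corresponding analysis assumes (coeval carbonate sub-samples
sharing a detrital contaminant, saturating ESR curves, partially bleached
equivalent-dose mixtures, ordered stratigraphic event series, crown
surface pairs with a known thickness field, multi-group landmark samples,
peptide-spectrum-match tables) and returns the ground truth alongside the
data so recovery tests can close the loop.

All randomness flows from one ``numpy.random.default_rng(seed)`` per call;
identical parameters and seed give bit-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .core import AgeEstimate, DecayConstants, Quantity, ValidationError
from . import esr as _esr
from . import gm as _gm
from . import lum as _lum
from . import proteo as _proteo
from . import useries as _useries
from .chronomodel import StratEvent

__all__ = [
    "GeneratorSpec", "gen_useries_set", "gen_esr_curve",
    "gen_de_distribution", "gen_strat_series", "gen_crown",
    "gen_landmark_groups", "gen_psm_table", "gen_us_esr_tooth",
    "default_template_paths", "DEFAULT_PROTEINS", "DEFAULT_SITE_PANEL",
    "AMELY_PEPTIDES",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Name + parameters + seed of one generator call (for provenance
    sidecars); equal specs produce bit-identical output."""

    kind: str
    params: dict
    seed: int

    def to_json(self) -> str:
        return json.dumps({"kind": self.kind, "params": self.params,
                           "seed": self.seed}, sort_keys=True, default=str)


# ---------------------------------------------------------------------------
# U-series

def gen_useries_set(true_age_kyr: float = 100.0, delta234_init: float = 500.0,
                    r0: float = 0.5,
                    contamination_fracs=(0.15, 0.3, 0.45, 0.6),
                    noise_rel: float = 0.02, seed: int | None = None,
                    k: DecayConstants = DecayConstants(),
                    convention: str = "equilibrium"):
    """Coeval carbonate sub-samples sharing one age and one detrital ratio.

    Each sub-sample carries a different detrital fraction (the fraction of
    the measured 230Th that is non-radiogenic).  Under the default
    ``equilibrium`` convention the detrital (230Th/232Th) is constant at
    ``r0``; under ``initial`` the detrital 230Th was incorporated at
    formation and has decayed.  Gaussian relative noise ``noise_rel``
    applies to the measured base ratios; the Th-normalised ratios stay
    mutually consistent.  Returns (measurements, truth).
    """
    if any(not 0.0 <= f < 1.0 for f in contamination_fracs):
        raise ValidationError("contamination fractions must be in [0, 1)")
    rng = np.random.default_rng(seed)
    t_yr = true_age_kyr * 1000.0
    a234 = 1.0 + (delta234_init / 1000.0) * math.exp(-k.lambda_234 * t_yr)
    a230_rad = float(_useries.forward_a230_238(t_yr, a234, k))
    decay = math.exp(-k.lambda_230 * t_yr) if convention == "initial" else 1.0

    out = []
    for i, f in enumerate(contamination_fracs):
        if f == 0.0:
            a232_238_true = 0.0
        else:
            a230_det = a230_rad * f / (1.0 - f)
            a232_238_true = a230_det / (r0 * decay)
        a230_true = a230_rad + (r0 * decay) * a232_238_true

        def jitter(v):
            return v * (1.0 + noise_rel * rng.standard_normal()) \
                if noise_rel > 0 else v

        a230 = jitter(a230_true)
        a234_m = jitter(a234)
        a232 = jitter(a232_238_true)
        if a232 > 0:
            a230_232 = a230 / a232
            a234_232 = a234_m / a232
            th_sds = (noise_rel * a230_232, noise_rel * a234_232)
        else:
            a230_232 = a234_232 = math.inf
            th_sds = (0.0, 0.0)
        out.append(_useries.USeriesMeasurement(
            a230_238=a230, a230_238_sd=noise_rel * a230,
            a234_238=a234_m, a234_238_sd=noise_rel * a234_m,
            a230_232=a230_232, a230_232_sd=th_sds[0],
            a234_232=a234_232, a234_232_sd=th_sds[1],
            label=f"SUB-{i + 1}"))
    truth = {"true_age_kyr": true_age_kyr, "r0": r0,
             "r0_effective": r0 * decay, "a234_238": a234,
             "a230_238_radiogenic": a230_rad, "convention": convention,
             "contamination_fracs": list(contamination_fracs)}
    return out, truth


# ---------------------------------------------------------------------------
# ESR

#: laboratory dose ladder mirroring exponentially increasing irradiation
#: times at ~0.23 Gy/s (first dose = 0 for the natural signal)
DEFAULT_ESR_DOSES = (0.0, 20.8, 90.1, 225.2, 436.8, 832.5, 1704.8, 2860.2)


def gen_esr_curve(i_max: float = 100.0, d0: float = 600.0, de: float = 500.0,
                  doses=DEFAULT_ESR_DOSES, noise_rel: float = 0.02,
                  seed: int | None = None):
    """Additive-dose SSE curve with multiplicative Gaussian noise."""
    if de < 0:
        raise ValidationError("de must be >= 0")
    rng = np.random.default_rng(seed)
    d = np.asarray(doses, float)
    clean = i_max * (1.0 - np.exp(-(d + de) / d0))
    noisy = clean * (1.0 + noise_rel * rng.standard_normal(d.size)) \
        if noise_rel > 0 else clean.copy()
    sd = np.maximum(noise_rel * np.abs(clean), 1e-9) if noise_rel > 0 else None
    curve = _esr.DoseResponseCurve(doses=d, intensities=noisy, intensity_sd=sd)
    truth = {"i_max": i_max, "d0": d0, "de": de, "noise_rel": noise_rel}
    return curve, truth


def gen_us_esr_tooth(age_kyr: float = 150.0, p_enamel: float = -0.5,
                     p_dentine: float = 0.0, a234_init: float = 1.2,
                     internal: float = 150.0, beta_dentine: float = 120.0,
                     beta_sediment: float = 150.0, gamma_external: float = 700.0,
                     cosmic: float = 80.0, rel_err: float = 0.05,
                     de_rel_err: float = 0.05,
                     k: DecayConstants = DecayConstants(),
                     quad_steps: int = 257):
    """Forward-model a tooth for US-ESR inversion tests.

    Tissue U-series ratios follow the uptake model at the given exponents;
    the equivalent dose is the dose accumulated under the uptake-scaled
    budget (dose rates in mGy/kyr).  ``rel_err``/``de_rel_err`` only set
    the quoted 1-sigma errors; the central values are noise-free.
    Returns (de, tissues, budget, truth).
    """
    en234, en230 = _esr.uptake_useries_ratios(p_enamel, age_kyr, k,
                                              a234_init, quad_steps)
    dn234, dn230 = _esr.uptake_useries_ratios(p_dentine, age_kyr, k,
                                              a234_init, quad_steps)
    rate = (beta_sediment + gamma_external + cosmic
            + internal * _esr.uptake_fraction_integral(p_enamel)
            + beta_dentine * _esr.uptake_fraction_integral(p_dentine))
    de_gy = rate * age_kyr / 1000.0

    def q(v, rel):
        return Quantity(v, rel * abs(v))

    tissues = [
        _esr.TissueUranium(tissue="enamel", u_ppm=q(2.0, rel_err),
                           a234_238=q(en234, rel_err), a230_238=q(en230, rel_err)),
        _esr.TissueUranium(tissue="dentine", u_ppm=q(30.0, rel_err),
                           a234_238=q(dn234, rel_err), a230_238=q(dn230, rel_err)),
    ]
    budget = _esr.DoseRateBudget(
        internal=q(internal, rel_err), beta_dentine=q(beta_dentine, rel_err),
        beta_sediment=q(beta_sediment, rel_err),
        gamma_external=q(gamma_external, rel_err), cosmic=q(cosmic, rel_err))
    de = _esr.EsrDe(de=de_gy, de_sd=de_rel_err * de_gy, d0=600.0, i_max=100.0)
    truth = {"age_kyr": age_kyr, "p_enamel": p_enamel, "p_dentine": p_dentine,
             "a234_init": a234_init, "de_gy": de_gy,
             "effective_rate_mgy_kyr": rate}
    return de, tissues, budget, truth


# ---------------------------------------------------------------------------
# luminescence

def gen_de_distribution(burial_dose: float = 500.0, od: float = 0.25,
                        n: int = 100, bleach_frac: float = 1.0,
                        inflation_max: float = 1500.0, rel_err: float = 0.1,
                        seed: int | None = None):
    """Single-grain De set: a bleached lognormal population around the
    burial dose (overdispersion ``od``) plus, for ``bleach_frac`` < 1,
    grains carrying uniformly distributed unbleached residual doses up to
    ``inflation_max``.  Returns (DeDistribution, truth)."""
    if n <= 0:
        raise ValidationError("n must be > 0")
    if not 0.0 < bleach_frac <= 1.0:
        raise ValidationError("bleach_frac must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n_bleached = int(round(bleach_frac * n))
    true_dose = burial_dose * np.exp(od * rng.standard_normal(n))
    n_inflated = n - n_bleached
    if n_inflated > 0:
        idx = rng.choice(n, size=n_inflated, replace=False)
        headroom = np.maximum(inflation_max - true_dose[idx], 0.0)
        true_dose[idx] += rng.uniform(0.0, 1.0, n_inflated) * headroom
    measured = true_dose * (1.0 + rel_err * rng.standard_normal(n))
    measured = np.maximum(measured, 1e-3)
    sigma = np.maximum(rel_err * measured, 1e-3)
    d = _lum.DeDistribution(de=measured, de_sigma=sigma, label="synthetic")
    truth = {"burial_dose": burial_dose, "od": od, "bleach_frac": bleach_frac,
             "inflation_max": inflation_max, "n": n, "rel_err": rel_err}
    return d, truth


def gen_fading_series(g_per_decade: float = 2.0, tc_h: float = 48.0,
                      delays_h=(48.0, 480.0, 4800.0, 48000.0),
                      noise: float = 0.0, seed: int | None = None):
    """Remnant-signal ratios decaying ``g_per_decade`` percent per decade
    of delay (exact when noise = 0)."""
    rng = np.random.default_rng(seed)
    delays = np.asarray(delays_h, float)
    ratios = 1.0 - (g_per_decade / 100.0) * np.log10(delays / tc_h)
    if noise > 0:
        ratios = ratios + noise * rng.standard_normal(delays.size)
    sd = np.full(delays.size, max(noise, 1e-3))
    series = _lum.FadingSeries(delays_h=delays, ratios=ratios, ratio_sd=sd,
                               tc_h=tc_h)
    return series, {"g_per_decade": g_per_decade, "tc_h": tc_h}


# ---------------------------------------------------------------------------
# stratigraphy

def gen_strat_series(true_boundaries=(200.0, 130.0), events_per_unit=4,
                     sigmas=10.0, roles=None, outer_margin: float = 40.0,
                     base_age: float = 150.0, seed: int | None = None):
    """Ordered event series over ``len(true_boundaries) + 1`` units.

    True event ages are uniform within each unit (outer units extend
    ``outer_margin`` kyr beyond their boundary); measurements are Gaussian
    around the true ages.  ``roles`` optionally assigns 'minimum'/'maximum'
    roles per unit; the dated auxiliary event is then offset to the
    appropriate side.  Returns (events, truth).
    """
    bounds = list(true_boundaries)
    if any(b2 >= b1 for b1, b2 in zip(bounds, bounds[1:])):
        raise ValidationError("boundaries must strictly decrease upward")
    n_units = len(bounds) + 1
    rng = np.random.default_rng(seed)
    if np.isscalar(events_per_unit):
        events_per_unit = [int(events_per_unit)] * n_units
    if np.isscalar(sigmas):
        sigmas = [float(sigmas)] * n_units
    if roles is None:
        roles = ["direct"] * n_units

    events = []
    theta_truth = []
    for u in range(n_units):
        if not bounds:                 # single unit: scatter around base_age
            lo, hi = base_age - outer_margin, base_age + outer_margin
        else:
            lo = bounds[u] if u < n_units - 1 else \
                max(bounds[-1] - outer_margin, 1.0)
            hi = bounds[u - 1] if u > 0 else bounds[0] + outer_margin
        for j in range(events_per_unit[u]):
            theta = rng.uniform(lo, hi)
            role = roles[u]
            if role == "direct":
                measured = rng.normal(theta, sigmas[u])
            elif role == "minimum":
                measured = rng.normal(theta - rng.uniform(0, outer_margin / 2),
                                      sigmas[u])
            elif role == "maximum":
                measured = rng.normal(theta + rng.uniform(0, outer_margin / 2),
                                      sigmas[u])
            else:
                raise ValidationError(f"unknown role {role!r}")
            events.append(StratEvent(
                estimate=AgeEstimate(age=float(measured), sigma=sigmas[u],
                                     role=role),
                unit=u, label=f"U{u}E{j}"))
            theta_truth.append(theta)
    truth = {"boundaries": bounds, "theta": theta_truth,
             "outer_margin": outer_margin}
    return events, truth


# ---------------------------------------------------------------------------
# crown surfaces

_CUSP_ANGLES = {"protoconid": 0.45, "metaconid": 2.0, "entoconid": 3.85,
                "hypoconid": 5.3}          # radians, lingual (ccw) order


def _superellipse_radius(phi, scale, exponent=2.5, aspect=0.88):
    c = np.abs(np.cos(phi)) ** exponent
    s = np.abs(np.sin(phi) / aspect) ** exponent
    return scale / (c + s) ** (1.0 / exponent)


@dataclass
class SyntheticCrown:
    """Crown surface pair with its analytic ground truth."""

    oes: "object"                      # trimesh.Trimesh
    edj: "object"
    edj_cap_faces: np.ndarray          # bool mask: EDJ faces on the top cap
    truth_volumes: "object"            # dental.TissueVolumes (dense quadrature)
    horns: np.ndarray                  # (4, 3) on the ridge path
    ridge_path: np.ndarray
    cervix_path: np.ndarray
    oes_cap_thickness: np.ndarray      # imposed thickness per OES cap vertex
    oes_cap_mask: np.ndarray           # OES vertices where the field applies
    params: dict = field(default_factory=dict)


def gen_crown(seed: int | None = None, scale_mm: float = 5.0,
              basin_height: float = 1.6,
              cusp_heights=(2.3, 1.8, 2.0, 2.1),
              cusp_width: float = 1.1, cusp_radius: float = 0.58,
              thickness_base: float = 0.45, thickness_amp: float = 0.0,
              n_r: int = 36, n_phi: int = 72,
              truth_factor: int = 5) -> SyntheticCrown:
    """Synthetic EDJ/OES crown pair.

    The EDJ is a smooth basin on a superellipsoidal footprint with four
    Gaussian dentine-horn bumps; the OES is the EDJ cap offset along its
    normals by a smooth positive thickness field
    t = thickness_base + thickness_amp * cos(phi - phi_hypoconid), closed
    by a skirt to the cervix plane.  Ground-truth volumes and the EDJ cap
    area come from the same construction at ``truth_factor`` times the
    resolution (dense surface quadrature).  ``seed`` only perturbs the
    cusp heights slightly, keeping the geometry reproducible.
    """
    import trimesh

    from .dental import TissueVolumes

    if thickness_base <= abs(thickness_amp):
        raise ValidationError("thickness field must stay positive")
    rng = np.random.default_rng(seed)
    heights = np.asarray(cusp_heights, float) * \
        (1.0 + 0.03 * rng.standard_normal(4) if seed is not None else 1.0)
    angles = np.array([_CUSP_ANGLES[n] for n in _gm.HORN_ORDER])
    centers = np.stack([
        cusp_radius * _superellipse_radius(a, scale_mm) * np.array(
            [np.cos(a), np.sin(a)]) for a in angles])
    w = cusp_width

    def z_of_xy(x, y):
        phi = np.arctan2(y, x)
        rr = np.hypot(x, y) / _superellipse_radius(phi, scale_mm)
        z = basin_height * np.clip(1.0 - rr ** 2, -1.0, 1.0)
        for h, c in zip(heights, centers):
            z = z + h * np.exp(-((x - c[0]) ** 2 + (y - c[1]) ** 2)
                               / (2.0 * w ** 2))
        return z * np.clip(1.0 - rr ** 8, 0.0, 1.0)

    def thickness_xy(x, y):
        phi = np.arctan2(y, x)
        return thickness_base + thickness_amp * np.cos(
            phi - _CUSP_ANGLES["hypoconid"])

    # curvature guard: offsetting along normals self-intersects when the
    # thickness exceeds the smallest concave (valley) radius of curvature
    # on the cap interior; the steep taper at the cervix rim is excluded
    # because rim vertices are not offset along their normals
    gx = np.linspace(-scale_mm, scale_mm, 60)
    xx, yy = np.meshgrid(gx, gx)
    phi_g = np.arctan2(yy, xx)
    rr_g = np.hypot(xx, yy) / _superellipse_radius(phi_g, scale_mm)
    h_fd = scale_mm / 200.0
    zc = z_of_xy(xx, yy)
    z_xx = (z_of_xy(xx + h_fd, yy) - 2 * zc + z_of_xy(xx - h_fd, yy)) / h_fd ** 2
    z_yy = (z_of_xy(xx, yy + h_fd) - 2 * zc + z_of_xy(xx, yy - h_fd)) / h_fd ** 2
    interior_g = rr_g < 0.8
    kappa = max(float(np.max(z_xx[interior_g])),
                float(np.max(z_yy[interior_g])), 0.0)
    t_max = thickness_base + abs(thickness_amp)
    if kappa > 0 and t_max >= 0.9 / kappa:
        raise ValidationError(
            f"thickness {t_max:.2f} mm exceeds the concave curvature radius "
            f"{1.0 / kappa:.2f} mm: the offset surface would self-intersect")

    def build(meshes_n_r, meshes_n_phi):
        r = np.linspace(0.0, 1.0, meshes_n_r + 1)[1:]
        phi = np.linspace(0.0, 2 * np.pi, meshes_n_phi, endpoint=False)
        pg, rg = np.meshgrid(phi, r)
        rad = _superellipse_radius(pg, scale_mm)
        x = (rg * rad * np.cos(pg)).ravel()
        y = (rg * rad * np.sin(pg)).ravel()
        z = z_of_xy(x, y)
        top = np.column_stack([x, y, z])
        apex = np.array([[0.0, 0.0, float(z_of_xy(0.0, 0.0))]])
        verts = np.vstack([apex, top])

        def vid(i_r, j_phi):
            return 1 + i_r * meshes_n_phi + (j_phi % meshes_n_phi)

        faces = []
        for j in range(meshes_n_phi):                   # centre fan
            faces.append([0, vid(0, j), vid(0, j + 1)])
        for i in range(meshes_n_r - 1):                 # rings
            for j in range(meshes_n_phi):
                a, b = vid(i, j), vid(i, j + 1)
                c, d = vid(i + 1, j), vid(i + 1, j + 1)
                faces.append([a, d, b])
                faces.append([a, c, d])
        n_cap_faces = len(faces)

        # bottom: flat fan at z=0 under the rim ring
        rim = [vid(meshes_n_r - 1, j) for j in range(meshes_n_phi)]
        base_idx = len(verts)
        bottom_rim = verts[rim].copy()
        bottom_rim[:, 2] = 0.0
        centre_idx = base_idx + meshes_n_phi
        verts = np.vstack([verts, bottom_rim, [[0.0, 0.0, 0.0]]])
        for j in range(meshes_n_phi):
            a = base_idx + j
            b = base_idx + (j + 1) % meshes_n_phi
            faces.append([centre_idx, b, a])
        for j in range(meshes_n_phi):                   # skirt rim -> bottom
            a, b = rim[j], rim[(j + 1) % meshes_n_phi]
            c, d = base_idx + j, base_idx + (j + 1) % meshes_n_phi
            faces.append([a, b, d])
            faces.append([a, d, c])
        cap_mask = np.zeros(len(faces), dtype=bool)
        cap_mask[:n_cap_faces] = True
        mesh = trimesh.Trimesh(vertices=verts, faces=np.array(faces),
                               process=False)
        return mesh, cap_mask

    def offset_mesh(edj_mesh, cap_mask_faces):
        import trimesh
        cap_vertex = np.zeros(len(edj_mesh.vertices), dtype=bool)
        cap_vertex[np.unique(edj_mesh.faces[cap_mask_faces])] = True
        v = edj_mesh.vertices.copy()
        # analytic graph normals for the cap: (-dz/dx, -dz/dy, 1)/|.|
        h2 = scale_mm * 1e-4
        x, y = v[:, 0], v[:, 1]
        zx = (z_of_xy(x + h2, y) - z_of_xy(x - h2, y)) / (2 * h2)
        zy = (z_of_xy(x, y + h2) - z_of_xy(x, y - h2)) / (2 * h2)
        norm = np.sqrt(zx ** 2 + zy ** 2 + 1.0)
        normals = np.column_stack([-zx, -zy, np.ones_like(zx)]) / norm[:, None]
        t = thickness_xy(x, y)
        off = v.copy()
        move = cap_vertex & (v[:, 2] > 1e-9)
        off[move] += normals[move] * t[move, None]
        # keep a closed solid: drop below-plane drift at the rim
        off[:, 2] = np.maximum(off[:, 2], 0.0)
        mesh = trimesh.Trimesh(vertices=off, faces=edj_mesh.faces.copy(),
                               process=False)
        return mesh, move, t

    edj, cap_faces = build(n_r, n_phi)
    oes, moved, t_field = offset_mesh(edj, cap_faces)

    # dense-quadrature truth from the same construction at high resolution
    edj_hi, cap_hi = build(n_r * truth_factor, n_phi * truth_factor)
    oes_hi, _, _ = offset_mesh(edj_hi, cap_hi)
    vcdp = float(edj_hi.volume)
    ve = float(oes_hi.volume) - vcdp
    sedj = float(edj_hi.area_faces[cap_hi].sum())
    truth_volumes = TissueVolumes(ve=ve, vcdp=vcdp, sedj=sedj)

    # ridge and cervix paths with the horn points exactly on the path
    phi_dense = np.linspace(0.0, 2 * np.pi, 720, endpoint=False)

    def path_at(phi_arr, r_frac):
        rad = _superellipse_radius(phi_arr, scale_mm) * r_frac
        x = rad * np.cos(phi_arr)
        y = rad * np.sin(phi_arr)
        return np.column_stack([x, y, z_of_xy(x, y)])

    ridge = path_at(phi_dense, cusp_radius)
    horns = path_at(angles, cusp_radius)
    phi_cervix = (phi_dense + _CUSP_ANGLES["protoconid"]) % (2 * np.pi)
    cervix = path_at(phi_cervix, 0.999)

    interior = moved & (np.hypot(oes.vertices[:, 0], oes.vertices[:, 1])
                        < 0.8 * scale_mm * 0.88)
    return SyntheticCrown(
        oes=oes, edj=edj, edj_cap_faces=cap_faces,
        truth_volumes=truth_volumes, horns=horns, ridge_path=ridge,
        cervix_path=cervix, oes_cap_thickness=t_field, oes_cap_mask=interior,
        params={"scale_mm": scale_mm, "thickness_base": thickness_base,
                "thickness_amp": thickness_amp, "n_r": n_r, "n_phi": n_phi})


# ---------------------------------------------------------------------------
# landmark groups

def default_template_paths(scale_mm: float = 5.0):
    """Analytic ridge/cervix paths + horns of an idealised EDJ (no mesh)."""
    phi = np.linspace(0.0, 2 * np.pi, 720, endpoint=False)
    angles = np.array([_CUSP_ANGLES[n] for n in _gm.HORN_ORDER])

    def z_ridge(a):
        z = 1.2 + 0.0 * a
        for name, h in zip(_gm.HORN_ORDER, (2.3, 1.8, 2.0, 2.1)):
            d = np.angle(np.exp(1j * (a - _CUSP_ANGLES[name])))
            z = z + h * np.exp(-d ** 2 / (2 * 0.45 ** 2))
        return z

    rad = _superellipse_radius(phi, scale_mm)
    ridge = np.column_stack([0.58 * rad * np.cos(phi),
                             0.58 * rad * np.sin(phi), z_ridge(phi)])
    horns_rad = _superellipse_radius(angles, scale_mm)
    horns = np.column_stack([0.58 * horns_rad * np.cos(angles),
                             0.58 * horns_rad * np.sin(angles),
                             z_ridge(angles)])
    phi_c = (phi + _CUSP_ANGLES["protoconid"]) % (2 * np.pi)
    rad_c = _superellipse_radius(phi_c, scale_mm)
    cervix = np.column_stack([rad_c * np.cos(phi_c), rad_c * np.sin(phi_c),
                              np.zeros_like(phi_c)])
    return horns, ridge, cervix


def _base_template(scale_mm: float = 5.0) -> _gm.LandmarkConfig:
    horns, ridge, cervix = default_template_paths(scale_mm)
    return _gm.build_template(horns, ridge, cervix, label="template")


def gen_landmark_groups(group_means=None, covariance_scale: float = 0.02,
                        n_per_group: int = 10, overlap: float = 0.0,
                        n_groups: int = 3, seed: int | None = None,
                        rigid_motions: bool = True):
    """Multi-group landmark sample with isotropic within-group noise.

    Group means default to smooth random deformations of the idealised EDJ
    template, with between-mean distances shrunk by ``overlap`` in [0, 1)
    (0 = well separated, -> 1 = coincident).  Each specimen is the group
    mean plus isotropic Gaussian noise (sd = covariance_scale * mean
    centroid size / sqrt(k)), optionally under a random rigid motion and
    scaling so Procrustes invariances are exercised.  Returns
    (configs, truth).
    """
    if not 0.0 <= overlap < 1.0:
        raise ValidationError("overlap must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if group_means is None:
        base = _base_template().coords
        k = base.shape[0]
        cs = math.sqrt(((base - base.mean(0)) ** 2).sum())
        means = []
        for gidx in range(n_groups):
            direction = rng.standard_normal((k, 3))
            # smooth the deformation so neighbouring landmarks move together
            kernel = np.exp(-np.linspace(-2, 2, 7) ** 2)
            kernel /= kernel.sum()
            for axis in range(3):
                direction[:, axis] = np.convolve(direction[:, axis],
                                                 kernel, mode="same")
            direction *= 0.035 * cs / np.sqrt((direction ** 2).sum())
            means.append(base + (1.0 - overlap) * direction)
    else:
        means = [np.asarray(m.coords if hasattr(m, "coords") else m, float)
                 for m in group_means]
        if len({m.shape for m in means}) > 1:
            raise ValidationError("group means must share the landmark count")
        k = means[0].shape[0]
        cs = math.sqrt(((means[0] - means[0].mean(0)) ** 2).sum())

    configs = []
    for gidx, mean in enumerate(means):
        gname = f"G{gidx + 1}"
        for j in range(n_per_group):
            pts = mean + covariance_scale * cs / math.sqrt(k) * \
                rng.standard_normal(mean.shape)
            if rigid_motions:
                q = rng.standard_normal((3, 3))
                qr, _ = np.linalg.qr(q)
                if np.linalg.det(qr) < 0:
                    qr[:, 0] = -qr[:, 0]
                pts = pts @ qr.T * rng.uniform(0.5, 2.0) \
                    + rng.uniform(-10, 10, 3)
            configs.append(_gm.LandmarkConfig(
                coords=pts, label=f"{gname}S{j + 1}", group=gname,
                n_points=k))
    truth = {"n_groups": len(means), "overlap": overlap,
             "covariance_scale": covariance_scale,
             "group_means": [m.tolist() for m in means]}
    return configs, truth


# ---------------------------------------------------------------------------
# proteomics

#: Synthetic stand-ins for enamel-proteome sequences (not real accessions;
#: hand-written to contain S-x-E phosphomotifs, N/Q deamidation targets and
#: a distinctive AMELY-specific stretch).
DEFAULT_PROTEINS = {
    "AMELX_SYN": ("MPLPPHPGHPGYINFSYEVLTPLKWYQSIRPPYPSYGYEPMGGW"
                  "LHHQIIPVLSQQHPPTHTLQPHHHIPVVPAQQPVIPQQPMMPVPGQHSME"),
    "AMELY_SYN": ("MPLPPHPGHPGYINFSYEVLTPLKWYQSMIRPPYSSYGADYGFMTSLQHHQ"
                  "IIPVVSQQHPPTHTLQPHHHIPVVPAQQPRIPQQPMMPVPGQHSMT"),
    "AMBN_SYN":  ("MKGLSLILLVLGTAFAVPAFPQQSGTPGMASLSLETMRQLGSLQGLNALSQ"
                  "YSRLGFGKALNSLWLHGLLPPHNSFPWIGPREHETQQYEYSLPVHPPPLPSQPSLQPHQ"),
    "ENAM_SYN":  ("MKTTILLFCLLGSTQSLPMFPQQSQTPREHDTNIPSEAHSIRSQEMPVNMP"
                  "RMPNVDMSQELSWQYQPQANQMDLSMFQGMDRPQTMSAEHPYSPQVHQ"),
    "MMP20_SYN": ("MKALSVLCLLQLTACLAYPLSGAAKEEDSNKDLAQQYLEKYYNLEKDVKQF"
                  "VRRKDSGPVVKKIREMQKFLGLEVTGKLDSDTLEVMRKPRCGVPDVGHFSSFPGMPKW"),
}

#: AMELY-specific reference peptides (synthetic; absent from AMELX_SYN
#: after I/L normalisation).
AMELY_PEPTIDES = ("SSYGADYGFMTSLQ", "SMIRPPYSSY")

#: Synthetic lineage-diagnostic panel on the toy sequences: position ->
#: expected residue per lineage.  The first three sites separate hominins
#: from the great-ape outgroups (the toy sequences carry the hominin
#: state); the last separates Denisovans from H. sapiens/Neanderthals.
DEFAULT_SITE_PANEL = _proteo.SitePanel(entries={
    ("ENAM_SYN", 20): {"H. sapiens": "F", "Neanderthal": "F",
                       "Denisovan": "F", "Xiahe-Denisovan": "F",
                       "Pan": "S", "Gorilla": "S"},
    ("ENAM_SYN", 44): {"H. sapiens": "Q", "Neanderthal": "Q",
                       "Denisovan": "Q", "Xiahe-Denisovan": "Q",
                       "Pan": "V", "Gorilla": "V"},
    ("AMBN_SYN", 30): {"H. sapiens": "A", "Neanderthal": "A",
                       "Denisovan": "A", "Xiahe-Denisovan": "A",
                       "Pan": "T", "Gorilla": "T"},
    ("AMELX_SYN", 40): {"H. sapiens": "P", "Neanderthal": "P",
                        "Denisovan": "S", "Xiahe-Denisovan": "S",
                        "Pan": "S", "Gorilla": "S"},
})

HOMO_LINEAGES = {"H. sapiens", "Neanderthal", "Denisovan", "Xiahe-Denisovan"}


def gen_psm_table(protein_set=None, n_psm: int = 200,
                  ptm_rates: dict | None = None,
                  motif_enrichment: float = 0.0,
                  diagnostic_sites_covered: bool = False,
                  site_panel: _proteo.SitePanel | None = None,
                  amely_present: bool = False, n_blank: int = 0,
                  support_prob: float = 0.85, seed: int | None = None):
    """Synthetic PSM table.

    Peptides are random windows of the configured protein sequences; each
    PTM in ``ptm_rates`` (name -> (target residues, rate)) is assigned so
    that the expected relative spectral count equals the rate.  With
    ``motif_enrichment`` > 0 phospho-serines prefer S positions with E at
    +2.  ``diagnostic_sites_covered`` adds supported PSMs spanning the
    panel sites; ``amely_present`` adds AMELY-specific peptides; blanks
    are contaminant-like PSMs flagged ``is_blank``.  Returns
    (psms, truth).
    """
    proteins = dict(protein_set or
                    {k: v for k, v in DEFAULT_PROTEINS.items()
                     if k != "AMELY_SYN"})
    ptm_rates = ptm_rates or {}
    for name, (_res, rate) in ptm_rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValidationError(f"rate for {name!r} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    names = sorted(proteins)
    psms: list[_proteo.PSM] = []

    def random_psm(protein, blank=False):
        seq = proteins[protein]
        length = int(rng.integers(9, 16))
        start = int(rng.integers(0, max(len(seq) - length, 1))) + 1
        pep = seq[start - 1:start - 1 + length]
        mods = []
        for mod_name, (residues, rate) in ptm_rates.items():
            positions = [i + 1 for i, aa in enumerate(pep) if aa in residues]
            if not positions:
                continue
            if rng.random() >= rate:
                continue
            if mod_name == _proteo.PHOSPHO and motif_enrichment > 0:
                sxe = [p for p in positions
                       if p + 1 < len(pep) and pep[p + 1] == "E"]
                if sxe and rng.random() < motif_enrichment:
                    positions = sxe
            mods.append((int(rng.choice(positions)), mod_name))
        support = {pos: bool(rng.random() < support_prob)
                   for pos, _m in mods}
        return _proteo.PSM(peptide=pep, protein=protein, start=start,
                           mods=mods, site_support=support, is_blank=blank)

    for _ in range(n_psm):
        psms.append(random_psm(names[int(rng.integers(len(names)))]))

    if diagnostic_sites_covered:
        panel = site_panel or DEFAULT_SITE_PANEL
        for (prot, pos), mapping in sorted(panel.entries.items()):
            if prot not in proteins:
                continue
            homo_states = {res for ln, res in mapping.items()
                           if ln in HOMO_LINEAGES}
            if diagnostic_sites_covered != "all" and len(homo_states) > 1:
                # mirror the study outcome: only sites where all hominin
                # lineages share the residue get supporting spectra
                continue
            seq = proteins[prot]
            start = max(pos - 5, 1)
            pep = seq[start - 1:start - 1 + 11]
            psms.append(_proteo.PSM(
                peptide=pep, protein=prot, start=start, mods=[],
                site_support={pos - start + 1: True}))

    if amely_present:
        full = dict(DEFAULT_PROTEINS)
        for ref in AMELY_PEPTIDES:
            start = full["AMELY_SYN"].find(ref) + 1
            psms.append(_proteo.PSM(peptide=ref, protein="AMELY_SYN",
                                    start=max(start, 1)))

    for _ in range(n_blank):
        psms.append(random_psm(names[int(rng.integers(len(names)))],
                               blank=True))

    truth = {"n_psm": n_psm, "ptm_rates": {k: [v[0], v[1]]
                                           for k, v in ptm_rates.items()},
             "motif_enrichment": motif_enrichment,
             "amely_present": amely_present, "n_blank": n_blank}
    return psms, truth


# ---------------------------------------------------------------------------
# file output (used by the CLI `simulate` subcommand)

def write_psm_tsv(psms, path) -> None:
    import pandas as pd

    rows = []
    for p in psms:
        rows.append({
            "peptide": p.peptide, "protein": p.protein, "start": p.start,
            "modifications": ";".join(f"{pos}:{name}" for pos, name in p.mods),
            "site_support": ";".join(f"{pos}:{int(flag)}"
                                     for pos, flag in p.site_support.items()),
            "is_blank": int(p.is_blank)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, default=str)
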