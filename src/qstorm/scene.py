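"""Ground-truth scene geometry and fluorophore placement.

A scene is a planar field (continuous nm coordinates, origin at the top-left
corner, x rightward, y downward) containing graphene-oxide (GO) regions,
fibres of known physical width and capsule shells.  Fluorophores are placed
on these structures (``specific``), uniformly over the field
(``nonspecific_background``) or in compact multi-fluorophore clusters
(``aggregate_member``); each placement carries its perpendicular gap distance
``z_gap`` to the GO plane, which downstream stages feed into the resonance
energy-transfer quenching law.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
from shapely.geometry import Polygon
from shapely import contains_xy

__all__ = [
    "GORegion",
    "Fibre",
    "Capsule",
    "SceneGeometry",
    "FluorophorePlacement",
    "AggregateParams",
    "make_scene",
    "place_fluorophores",
    "placements_to_arrays",
]

NM_PER_UM = 1000.0
UM2_PER_NM2 = 1e-6

#: default fibre width from AFM measurements of I3K peptide fibrils
DEFAULT_FIBRE_WIDTH_NM = 11.0


@dataclass(frozen=True)
class GORegion:
    """A polygonal graphene-oxide patch.

    ``thickness_nm`` ~1 nm for a monolayer flake, ~5 nm for a stacked film;
    ``absorption_per_nm`` is the fraction of incident light absorbed per nm
    of film (used only for transmission bookkeeping, not for quenching).
    """

    vertices: tuple[tuple[float, float], ...]
    thickness_nm: float = 1.0
    absorption_per_nm: float = 0.0045

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area_nm2(self) -> float:
        return self.polygon().area


@dataclass(frozen=True)
class Fibre:
    """A fibre backbone polyline with a physical width."""

    points: tuple[tuple[float, float], ...]
    width_nm: float = DEFAULT_FIBRE_WIDTH_NM

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ValueError("fibre width must be positive")
        if len(self.points) < 2:
            raise ValueError("fibre backbone needs at least 2 points")

    @property
    def length_nm(self) -> float:
        pts = np.asarray(self.points)
        return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))


@dataclass(frozen=True)
class Capsule:
    """A capsule shell: annulus between inner and outer radius (2-D projection)."""

    centre: tuple[float, float]
    inner_radius_nm: float
    outer_radius_nm: float

    def __post_init__(self) -> None:
        if not (self.outer_radius_nm > self.inner_radius_nm >= 0):
            raise ValueError("capsule requires outer radius > inner radius >= 0")

    @property
    def shell_thickness_nm(self) -> float:
        return self.outer_radius_nm - self.inner_radius_nm

    @property
    def area_nm2(self) -> float:
        return math.pi * (self.outer_radius_nm**2 - self.inner_radius_nm**2)


@dataclass
class SceneGeometry:
    """Field geometry: GO regions, fibres and capsule shells, all in nm."""

    field_size: tuple[float, float]
    go_regions: list[GORegion] = field(default_factory=list)
    fibres: list[Fibre] = field(default_factory=list)
    capsules: list[Capsule] = field(default_factory=list)
    substrate_label: str = "glass"

    def __post_init__(self) -> None:
        w, h = self.field_size
        if w <= 0 or h <= 0:
            raise ValueError("field size must be positive")
        for reg in self.go_regions:
            self._check_inside(np.asarray(reg.vertices), "GO region vertex")
        for fib in self.fibres:
            self._check_inside(np.asarray(fib.points), "fibre backbone point")
        for cap in self.capsules:
            cx, cy = cap.centre
            r = cap.outer_radius_nm
            if not (0 <= cx - r and cx + r <= w and 0 <= cy - r and cy + r <= h):
                raise ValueError("capsule shell exits the field")

    def _check_inside(self, pts: np.ndarray, what: str) -> None:
        w, h = self.field_size
        if pts.size == 0:
            return
        if (pts[:, 0] < 0).any() or (pts[:, 0] > w).any() or (
            pts[:, 1] < 0
        ).any() or (pts[:, 1] > h).any():
            raise ValueError(f"{what} outside the field bounds")

    # -- membership ---------------------------------------------------------
    def go_membership(self) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
        """Vectorized (x, y) -> bool test for being over any GO region.

        Points on a polygon boundary count as inside (covers semantics), so
        membership is deterministic for overlapping regions.
        """
        # tiny outward buffer makes boundary points unambiguous members
        polys = [r.polygon().buffer(1e-6) for r in self.go_regions]

        def member(x: np.ndarray, y: np.ndarray) -> np.ndarray:
            x = np.asarray(x, dtype=float)
            y = np.asarray(y, dtype=float)
            out = np.zeros(np.broadcast(x, y).shape, dtype=bool)
            for p in polys:
                out |= contains_xy(p, x, y)
            return out

        return member

    def go_mask(self, pixel_nm: float) -> np.ndarray:
        """Rasterize GO membership on half-open pixel bins [i*p, (i+1)*p).

        Pixel (row, col) is tested at its centre.
        """
        w, h = self.field_size
        ncol = int(np.ceil(w / pixel_nm))
        nrow = int(np.ceil(h / pixel_nm))
        xs = (np.arange(ncol) + 0.5) * pixel_nm
        ys = (np.arange(nrow) + 0.5) * pixel_nm
        xx, yy = np.meshgrid(xs, ys)
        return self.go_membership()(xx.ravel(), yy.ravel()).reshape(nrow, ncol)

    @property
    def go_area_nm2(self) -> float:
        from shapely.ops import unary_union

        if not self.go_regions:
            return 0.0
        return unary_union([r.polygon() for r in self.go_regions]).area

    # -- serialization ------------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "units": {"length": "nm"},
            "field_size": list(self.field_size),
            "substrate_label": self.substrate_label,
            "go_regions": [asdict(r) for r in self.go_regions],
            "fibres": [asdict(f) for f in self.fibres],
            "capsules": [asdict(c) for c in self.capsules],
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str) -> "SceneGeometry":
        try:
            payload = json.loads(source)
        except json.JSONDecodeError:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            field_size=tuple(payload["field_size"]),
            go_regions=[
                GORegion(
                    vertices=tuple(tuple(v) for v in r["vertices"]),
                    thickness_nm=r["thickness_nm"],
                    absorption_per_nm=r["absorption_per_nm"],
                )
                for r in payload["go_regions"]
            ],
            fibres=[
                Fibre(points=tuple(tuple(p) for p in f["points"]), width_nm=f["width_nm"])
                for f in payload["fibres"]
            ],
            capsules=[
                Capsule(
                    centre=tuple(c["centre"]),
                    inner_radius_nm=c["inner_radius_nm"],
                    outer_radius_nm=c["outer_radius_nm"],
                )
                for c in payload["capsules"]
            ],
            substrate_label=payload.get("substrate_label", "glass"),
        )


@dataclass(frozen=True)
class FluorophorePlacement:
    """A single fluorophore: position, gap distance to the GO plane, emission."""

    x: float
    y: float
    z_gap: float
    wavelength_nm: float = 570.0
    photon_budget_mean: float = 1000.0
    role_tag: str = "specific"
    aggregate_id: int | None = None

    def __post_init__(self) -> None:
        if self.z_gap <= 0:
            raise ValueError("z_gap must be positive (fluorophore above the GO plane)")
        if self.wavelength_nm <= 0 or self.photon_budget_mean <= 0:
            raise ValueError("wavelength and photon budget must be positive")
        if self.role_tag not in {"specific", "nonspecific_background", "aggregate_member"}:
            raise ValueError(f"unknown role_tag {self.role_tag!r}")


@dataclass(frozen=True)
class AggregateParams:
    """Surface-adsorbed dye clusters: Poisson number of clusters per area,
    member count 2 + Poisson(size_mean - 2), members uniform in a disc."""

    rate_per_um2: float = 0.0
    size_mean: float = 5.0
    radius_nm: float = 30.0
    photon_budget_mean: float = 1000.0

    def __post_init__(self) -> None:
        if self.rate_per_um2 < 0 or self.radius_nm <= 0 or self.size_mean < 2:
            raise ValueError("invalid aggregate parameters")


# ---------------------------------------------------------------------------
# scene templates


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Per-operation stream split of a single global seed.

    The stream label is hashed with CRC32 so splits are stable across
    processes (Python's built-in ``hash`` is salted per interpreter).
    """
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stream.encode()) % (2**31)])
    return np.random.default_rng(ss)


def _smooth_backbone(
    rng: np.random.Generator,
    field: tuple[float, float],
    step_nm: float = 50.0,
    curvature_sd: float = 0.08,
    margin: float = 100.0,
    max_steps: int = 400,
) -> np.ndarray:
    """Random smooth polyline: a persistent walk whose heading diffuses slowly.

    Stops when leaving the margin-inset field; retried by the caller if too
    short.
    """
    w, h = field
    x = rng.uniform(margin, w - margin)
    y = rng.uniform(margin, h - margin)
    heading = rng.uniform(0, 2 * np.pi)
    pts = [(x, y)]
    for _ in range(max_steps):
        heading += rng.normal(0.0, curvature_sd)
        x += step_nm * np.cos(heading)
        y += step_nm * np.sin(heading)
        if not (margin <= x <= w - margin and margin <= y <= h - margin):
            break
        pts.append((x, y))
    return np.asarray(pts)


def make_scene(template: str, seed: int = 0, **params) -> SceneGeometry:
    """Build one of the three specimen-class scenes.

    Templates
    ---------
    ``go_sheet``
        A single square GO flake (monolayer, ~1 nm) under a uniform dye
        layer.  Parameters: ``field_nm`` (default 10000), ``flake_size_nm``
        (default 4000), ``flake_thickness_nm`` (default 1).
    ``fibres_over_flake``
        Fibres of physical width ``fibre_width_nm`` (default 11) crossing a
        field whose left ``flake_fraction`` (default 0.5) is covered by a GO
        flake.  Parameters: ``n_fibres`` (default 3), ``field_nm``.
    ``capsules_on_film``
        Capsule shells on a GO film covering the whole field.  Parameters:
        ``n_capsules`` (default 2), ``inner_radius_nm`` (default 500),
        ``shell_thickness_nm`` (default 300, within the observed 200-400 nm
        capsule-thickness range), ``film_thickness_nm`` (default 5),
        ``field_nm``.
    """
    rng = _rng(seed, f"make_scene:{template}")
    field_nm = float(params.pop("field_nm", 10_000.0))
    fs = (field_nm, field_nm)

    if template == "go_sheet":
        size = float(params.pop("flake_size_nm", 4_000.0))
        thick = float(params.pop("flake_thickness_nm", 1.0))
        _reject_unknown(params)
        if size > field_nm:
            raise ValueError("flake larger than the field")
        x0 = rng.uniform(0, field_nm - size)
        y0 = rng.uniform(0, field_nm - size)
        flake = GORegion(
            vertices=((x0, y0), (x0 + size, y0), (x0 + size, y0 + size), (x0, y0 + size)),
            thickness_nm=thick,
        )
        return SceneGeometry(field_size=fs, go_regions=[flake])

    if template == "fibres_over_flake":
        n_fibres = int(params.pop("n_fibres", 3))
        width = float(params.pop("fibre_width_nm", DEFAULT_FIBRE_WIDTH_NM))
        frac = float(params.pop("flake_fraction", 0.5))
        thick = float(params.pop("flake_thickness_nm", 1.0))
        _reject_unknown(params)
        if not 0 < frac <= 1:
            raise ValueError("flake_fraction must be in (0, 1]")
        flake = GORegion(
            vertices=(
                (0.0, 0.0),
                (frac * field_nm, 0.0),
                (frac * field_nm, field_nm),
                (0.0, field_nm),
            ),
            thickness_nm=thick,
        )
        fibres = []
        while len(fibres) < n_fibres:
            pts = _smooth_backbone(rng, fs)
            if len(pts) >= 20:  # at least ~1 um of backbone
                fibres.append(Fibre(points=tuple(map(tuple, pts)), width_nm=width))
        return SceneGeometry(field_size=fs, go_regions=[flake], fibres=fibres)

    if template == "capsules_on_film":
        n_caps = int(params.pop("n_capsules", 2))
        inner = float(params.pop("inner_radius_nm", 500.0))
        shell = float(params.pop("shell_thickness_nm", 300.0))
        film_thick = float(params.pop("film_thickness_nm", 5.0))
        _reject_unknown(params)
        outer = inner + shell
        if 2 * outer > field_nm:
            raise ValueError("capsule does not fit in the field")
        film = GORegion(
            vertices=((0.0, 0.0), (field_nm, 0.0), (field_nm, field_nm), (0.0, field_nm)),
            thickness_nm=film_thick,
        )
        caps: list[Capsule] = []
        attempts = 0
        while len(caps) < n_caps:
            attempts += 1
            if attempts > 1000:
                raise ValueError("cannot place non-overlapping capsules in the field")
            cx = rng.uniform(outer, field_nm - outer)
            cy = rng.uniform(outer, field_nm - outer)
            if all(
                np.hypot(cx - c.centre[0], cy - c.centre[1]) > 2 * outer for c in caps
            ):
                caps.append(Capsule((cx, cy), inner, outer))
        return SceneGeometry(field_size=fs, go_regions=[film], capsules=caps)

    raise ValueError(f"unknown scene template {template!r}")


def _reject_unknown(params: dict) -> None:
    if params:
        raise TypeError(f"unknown template parameters: {sorted(params)}")


# ---------------------------------------------------------------------------
# fluorophore placement


def place_fluorophores(
    scene: SceneGeometry,
    densities: dict[str, float] | None = None,
    spacer_thickness_nm: float = 2.0,
    aggregate_params: AggregateParams | None = None,
    seed: int = 0,
    *,
    wavelength_nm: float = 570.0,
    photon_budget_mean: float = 1000.0,
    capsule_height_nm: float = 500.0,
) -> list[FluorophorePlacement]:
    """Sample fluorophore placements for a scene.

    ``densities`` maps roles to surface densities in um^-2:

    * ``"specific"`` decorates fibres (uniform along backbone, transverse
      offset uniform across the width) and capsule shells (uniform on the
      annulus); counts are Poisson with mean density x structure area.
      Fibre dyes sit at ``z_gap = spacer + u`` with u uniform in
      [0, width] (dye anywhere on the fibre body); capsule dyes sit at
      ``z_gap = capsule_height_nm`` (the imaged slice through the bacterium,
      far outside the efficient quenching range).
    * ``"nonspecific_background"`` is uniform over the field at
      ``z_gap = spacer_thickness_nm``.
    * aggregates (``aggregate_params``) are cluster artefacts at the surface,
      ``z_gap = spacer_thickness_nm``.
    """
    densities = dict(densities or {})
    if spacer_thickness_nm <= 0:
        raise ValueError("spacer thickness must be positive")
    unknown = set(densities) - {"specific", "nonspecific_background"}
    if unknown:
        raise ValueError(f"unknown density roles: {sorted(unknown)}")
    if any(d < 0 for d in densities.values()):
        raise ValueError("densities must be non-negative")
    w, h = scene.field_size
    field_area_um2 = w * h * UM2_PER_NM2
    if field_area_um2 <= 0:
        raise ValueError("zero-area scene")

    rng = _rng(seed, "place_fluorophores")
    out: list[FluorophorePlacement] = []

    common = dict(wavelength_nm=wavelength_nm, photon_budget_mean=photon_budget_mean)

    # specific: fibres
    rho_s = densities.get("specific", 0.0)
    if rho_s > 0:
        for fib in scene.fibres:
            area_um2 = fib.length_nm * fib.width_nm * UM2_PER_NM2
            n = rng.poisson(rho_s * area_um2)
            if n == 0:
                continue
            pts = np.asarray(fib.points)
            seg = np.diff(pts, axis=0)
            seg_len = np.hypot(seg[:, 0], seg[:, 1])
            cum = np.concatenate([[0.0], np.cumsum(seg_len)])
            s = rng.uniform(0, cum[-1], n)
            idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
            t = (s - cum[idx]) / seg_len[idx]
            base = pts[idx] + t[:, None] * seg[idx]
            tang = seg[idx] / seg_len[idx][:, None]
            normal = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
            off = rng.uniform(-fib.width_nm / 2, fib.width_nm / 2, n)
            xy = base + off[:, None] * normal
            z = spacer_thickness_nm + rng.uniform(0, fib.width_nm, n)
            for (px, py), pz in zip(xy, z):
                if 0 <= px <= w and 0 <= py <= h:
                    out.append(
                        FluorophorePlacement(px, py, pz, role_tag="specific", **common)
                    )
        # specific: capsule shells
        for cap in scene.capsules:
            n = rng.poisson(rho_s * cap.area_nm2 * UM2_PER_NM2)
            if n == 0:
                continue
            # uniform on the annulus: r ~ sqrt(U) between radii
            r = np.sqrt(
                rng.uniform(cap.inner_radius_nm**2, cap.outer_radius_nm**2, n)
            )
            th = rng.uniform(0, 2 * np.pi, n)
            px = cap.centre[0] + r * np.cos(th)
            py = cap.centre[1] + r * np.sin(th)
            for xi, yi in zip(px, py):
                out.append(
                    FluorophorePlacement(
                        xi, yi, capsule_height_nm, role_tag="specific", **common
                    )
                )

    # nonspecific background
    rho_b = densities.get("nonspecific_background", 0.0)
    if rho_b > 0:
        n = rng.poisson(rho_b * field_area_um2)
        px = rng.uniform(0, w, n)
        py = rng.uniform(0, h, n)
        for xi, yi in zip(px, py):
            out.append(
                FluorophorePlacement(
                    xi, yi, spacer_thickness_nm, role_tag="nonspecific_background", **common
                )
            )

    # aggregates
    if aggregate_params is not None and aggregate_params.rate_per_um2 > 0:
        ap = aggregate_params
        n_clusters = rng.poisson(ap.rate_per_um2 * field_area_um2)
        for cid in range(n_clusters):
            cx = rng.uniform(0, w)
            cy = rng.uniform(0, h)
            k = 2 + rng.poisson(max(ap.size_mean - 2.0, 0.0))
            r = ap.radius_nm * np.sqrt(rng.uniform(0, 1, k))
            th = rng.uniform(0, 2 * np.pi, k)
            for xi, yi in zip(cx + r * np.cos(th), cy + r * np.sin(th)):
                if 0 <= xi <= w and 0 <= yi <= h:
                    out.append(
                        FluorophorePlacement(
                            xi,
                            yi,
                            spacer_thickness_nm,
                            wavelength_nm=wavelength_nm,
                            photon_budget_mean=ap.photon_budget_mean,
                            role_tag="aggregate_member",
                            aggregate_id=cid,
                        )
                    )
    return out


def placements_to_arrays(placements: Sequence[FluorophorePlacement]) -> dict[str, np.ndarray]:
    """Columnar view of a placement list for vectorized simulation."""
    return {
        "x": np.array([p.x for p in placements], dtype=float),
        "y": np.array([p.y for p in placements], dtype=float),
        "z_gap": np.array([p.z_gap for p in placements], dtype=float),
        "wavelength_nm": np.array([p.wavelength_nm for p in placements], dtype=float),
        "photon_budget_mean": np.array(
            [p.photon_budget_mean for p in placements], dtype=float
        ),
        "role_tag": np.array([p.role_tag for p in placements]),
    }
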