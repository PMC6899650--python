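"""Ground-truthed synthetic fossil-bed communities.

Generates bedding-plane census maps with known spatial structure so every
analysis stage can be validated without field data: each taxon is drawn
from a named point process (CSR, heterogeneous Poisson, Thomas cluster,
double Thomas, or inhomogeneous Thomas), decorated with lognormal body
sizes, then optionally distorted the way real surfaces are — a tectonic
pure shear of the whole map and a differential-erosion thinning with a
spatial retention gradient.  The returned ground truth records every
generator parameter and each specimen's erosion survival, so calibration
tests can recompute their own expectations.

The built-in scenario bank spans the study-surface ranges: mapped windows
from below 1 m² to ~115 m², specimen densities from a few to ~100 per m²,
and per-taxon abundances from tens to thousands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .clusters import (
    DoubleThomasParams,
    ThomasParams,
    simulate_double_thomas,
    simulate_inhom_thomas,
    simulate_thomas,
)
from .geometry import (
    BedSurfaceMap,
    ObservationWindow,
    SpecimenRecord,
    StrainEstimate,
    _strain_matrix,
    _transform_map,
)
from .nullmodels import CallableIntensity, as_rng, simulate_csr, simulate_heterogeneous_poisson

PROCESSES = ("CSR", "HP", "TC", "DTC", "ITC")


@dataclass
class ErosionSpec:
    """Forward model of differential erosion: retention ∝ exp(b·covariate)."""

    kind: str  # gradient_x | gradient_y | radial
    b: float
    anchor: tuple[float, float] | None = None

    def covariate(self, x, y) -> np.ndarray:
        if self.kind == "gradient_x":
            return np.asarray(x, float)
        if self.kind == "gradient_y":
            return np.asarray(y, float)
        if self.kind == "radial":
            ax, ay = self.anchor
            return np.hypot(np.asarray(x, float) - ax, np.asarray(y, float) - ay)
        raise ValueError(self.kind)

    def retention(self, x, y, window: ObservationWindow) -> np.ndarray:
        """exp(b·z) normalised so the maximum over the window is 1."""
        z = self.covariate(x, y)
        xmin, ymin, xmax, ymax = window.bounds
        gx, gy = np.meshgrid(
            np.linspace(xmin, xmax, 101), np.linspace(ymin, ymax, 101), indexing="ij"
        )
        zg = self.covariate(gx.ravel(), gy.ravel())
        inside = window.contains(gx.ravel(), gy.ravel())
        zmax = float((self.b * zg[inside]).max())
        return np.exp(self.b * z - zmax)


@dataclass
class TaxonSpec:
    """One synthetic taxon: its generating process and target abundance."""

    taxon: str
    process: str
    target_n: int
    params: dict = field(default_factory=dict)
    # lognormal body-size model: (median metres, log-sd) for the frond and disc
    size_distribution: tuple[float, float] = (0.05, 0.4)
    group_class: str = "described_taxon"

    def __post_init__(self):
        if self.process not in PROCESSES:
            raise ValueError(f"unknown process {self.process!r}")
        if self.target_n < 0:
            raise ValueError("target_n must be >= 0")


@dataclass
class CommunitySpec:
    """A whole synthetic surface: window, taxa, and taphonomic distortions."""

    name: str
    window: ObservationWindow
    taxa: list[TaxonSpec]
    strain: StrainEstimate | None = None
    erosion: ErosionSpec | None = None
    seed: int | None = None

    def expected_density(self) -> float:
        return sum(t.target_n for t in self.taxa) / self.window.area

    def validate(self) -> None:
        import warnings

        d = self.expected_density()
        if self.taxa and not (0.5 <= d <= 150.0):
            warnings.warn(
                f"expected density {d:.2f} ind/m² outside the plausible 0.5–150 band",
                stacklevel=2,
            )


@dataclass
class GroundTruth:
    """Everything needed to recompute the expectations a scenario implies."""

    spec: CommunitySpec
    seed: int | None
    taxa: dict[str, dict] = field(default_factory=dict)  # per-taxon process/params/n
    survival: dict[str, bool] = field(default_factory=dict)  # specimen_id -> survived erosion


def _hp_surface(params: dict, window: ObservationWindow) -> CallableIntensity:
    spec = ErosionSpec(params.get("kind", "gradient_x"), params["b"], params.get("anchor"))
    return CallableIntensity(lambda x, y: spec.retention(x, y, window), kind="gradient")


def _simulate_taxon(
    t: TaxonSpec, window: ObservationWindow, rng: np.random.Generator
) -> tuple[np.ndarray, dict]:
    lam = t.target_n / window.area
    if t.process == "CSR":
        return simulate_csr(window, n=t.target_n, seed=rng), {}
    if t.process == "HP":
        surface = _hp_surface(t.params, window)
        return (
            simulate_heterogeneous_poisson(surface, window, seed=rng, n=t.target_n),
            {"surface": t.params},
        )
    if t.process == "TC":
        p = ThomasParams(t.params["sigma"], t.params["rho"], lam)
        return simulate_thomas(p, window, seed=rng), {"thomas": p}
    if t.process == "DTC":
        large = ThomasParams(
            t.params["sigma_large"],
            t.params["rho_large"],
            t.params["rho_large"] * t.params["mu_large"],
        )
        p = DoubleThomasParams(
            large, t.params["sigma_small"], lam / large.lambda_total
        )
        return simulate_double_thomas(p, window, seed=rng), {"double_thomas": p}
    if t.process == "ITC":
        p = ThomasParams(t.params["sigma"], t.params["rho"], lam)
        surface = _hp_surface(t.params["surface"], window)
        pts = simulate_inhom_thomas(p, surface, window, seed=rng, compensate=True)
        return pts, {"thomas": p, "surface": t.params["surface"]}
    raise ValueError(t.process)


def _attach_sizes(
    taxon: TaxonSpec, pts: np.ndarray, rng: np.random.Generator, id_offset: int
) -> list[SpecimenRecord]:
    median, log_sd = taxon.size_distribution
    n = len(pts)
    fronds = np.exp(rng.normal(math.log(median), log_sd, n))
    discs = np.exp(rng.normal(math.log(median / 3), log_sd, n))
    recs = []
    for k in range(n):
        recs.append(
            SpecimenRecord(
                specimen_id=f"s{id_offset + k:06d}",
                taxon=taxon.taxon,
                x=float(pts[k, 0]),
                y=float(pts[k, 1]),
                frond_length=float(fronds[k]),
                frond_width=float(fronds[k] * 0.5),
                disc_width=float(discs[k]),
                disc_length=float(discs[k]),
                group_class=taxon.group_class,
            )
        )
    return recs


def apply_tectonic_strain(
    surface_map: BedSurfaceMap, strain: StrainEstimate, area_preserving: bool = True
) -> BedSurfaceMap:
    """Forward tectonic distortion: pure shear of coordinates and disc axes.

    Circular discs become ellipses with aspect ratio exactly
    ``strain.ratio`` and long axis along ``strain.orientation``; the exact
    inverse of :func:`sppa.geometry.retrodeform`.
    """
    fwd = _strain_matrix(strain, area_preserving)
    if area_preserving:
        scale = (math.sqrt(strain.ratio), 1.0 / math.sqrt(strain.ratio))
    else:
        scale = (strain.ratio, 1.0)
    return _transform_map(surface_map, fwd, scale)


def apply_erosion_thinning(
    surface_map: BedSurfaceMap, erosion: ErosionSpec, seed=None
) -> tuple[BedSurfaceMap, dict[str, bool]]:
    """Thin a map by spatially varying retention; returns (map, survival)."""
    rng = as_rng(seed)
    if not surface_map.records:
        return surface_map, {}
    xy = surface_map.coords()
    ret = erosion.retention(xy[:, 0], xy[:, 1], surface_map.window)
    keep = rng.uniform(0, 1, len(ret)) < ret
    survival = {
        r.specimen_id: bool(k) for r, k in zip(surface_map.records, keep)
    }
    kept = [r for r, k in zip(surface_map.records, keep) if k]
    return surface_map.subset(kept), survival


def generate_community(
    spec: CommunitySpec, seed: int | None = None
) -> tuple[BedSurfaceMap, GroundTruth]:
    """Generate one ground-truthed surface from a community specification.

    Per-taxon patterns come from the named simulators, body sizes are
    attached, then strain and erosion are applied in that order.  The same
    spec and seed always reproduce the identical map.
    """
    spec.validate()
    seed = spec.seed if seed is None else seed
    rng = as_rng(seed)
    truth = GroundTruth(spec=spec, seed=seed)
    records: list[SpecimenRecord] = []
    for t in spec.taxa:
        pts, detail = _simulate_taxon(t, spec.window, rng)
        recs = _attach_sizes(t, pts, rng, id_offset=len(records))
        records.extend(recs)
        truth.taxa[t.taxon] = {
            "process": t.process,
            "params": dict(t.params),
            "detail": detail,
            "target_n": t.target_n,
            "generated_n": len(recs),
            "group_class": t.group_class,
        }
    out = BedSurfaceMap(spec.name, records, spec.window)
    if spec.erosion is not None:
        out, survival = apply_erosion_thinning(out, spec.erosion, rng)
        truth.survival = survival
        for t in spec.taxa:
            truth.taxa[t.taxon]["surviving_n"] = sum(
                1 for r in out.records if r.taxon == t.taxon
            )
    if spec.strain is not None:
        out = apply_tectonic_strain(out, spec.strain)
    return out, truth


# ---------------------------------------------------------------------------
# Scenario bank
# ---------------------------------------------------------------------------


def scenario(name: str, seed: int | None = None) -> CommunitySpec:
    """Named community scenarios spanning the study-surface ranges.

    ``bed_b_like``      large sparse surface (≈115 m², 3 abundant taxa);
    ``e_surface_like``  large dense surface (≈85 m², 6 abundant taxa,
                        mixed processes);
    ``d_surface_like``  ≈71 m², one dominant clustered taxon;
    ``bristy_cove_like`` tiny dense quadrat (< 1 m², ~100 ind);
    ``spaniards_bay_like`` small sparse surface (≈16 m², low-n taxa,
                        habitat-associated processes).
    """
    bank = {
        "bed_b_like": _bed_b_like,
        "e_surface_like": _e_surface_like,
        "d_surface_like": _d_surface_like,
        "bristy_cove_like": _bristy_cove_like,
        "spaniards_bay_like": _spaniards_bay_like,
    }
    if name not in bank:
        raise KeyError(f"unknown scenario {name!r}; choose from {sorted(bank)}")
    spec = bank[name]()
    spec.seed = seed
    return spec


def _bed_b_like() -> CommunitySpec:
    window = ObservationWindow.rectangle(0, 0, 13.0, 8.858)  # ≈115.2 m²
    taxa = [
        TaxonSpec("Charniodiscus_like", "TC", 48, {"sigma": 0.15, "rho": 0.15},
                  size_distribution=(0.08, 0.4)),
        TaxonSpec("Primocandelabrum_like", "TC", 106, {"sigma": 0.25, "rho": 0.05},
                  size_distribution=(0.1, 0.4)),
        TaxonSpec("Charnia_like", "TC", 69, {"sigma": 0.2, "rho": 0.06},
                  size_distribution=(0.12, 0.4)),
        TaxonSpec("holdfast_disc", "CSR", 25, group_class="bin_group"),
        TaxonSpec("ivesheadiomorph", "CSR", 40, group_class="taphomorph"),
    ]
    return CommunitySpec("bed_b_like", window, taxa)


def _e_surface_like() -> CommunitySpec:
    window = ObservationWindow.rectangle(0, 0, 10.4, 8.214)  # ≈85.4 m²
    taxa = [
        TaxonSpec("Fractofusus_like", "TC", 1137, {"sigma": 0.12, "rho": 1.1},
                  size_distribution=(0.06, 0.35)),
        TaxonSpec("Charniodiscus_like", "TC", 326, {"sigma": 0.1, "rho": 1.8},
                  size_distribution=(0.08, 0.4)),
        TaxonSpec("feather_duster", "DTC", 272,
                  {"sigma_large": 0.5, "rho_large": 0.08, "mu_large": 7.0,
                   "sigma_small": 0.08}),
        TaxonSpec("Beothukis_like", "HP", 76, {"kind": "gradient_x", "b": 0.35}),
        TaxonSpec("Thectardis_like", "CSR", 39),
        TaxonSpec("Bradgatia_like", "CSR", 34),
        TaxonSpec("Hiemalora_like", "CSR", 20, group_class="organ_taxon"),
        TaxonSpec("ivesheadiomorph", "CSR", 60, group_class="taphomorph"),
    ]
    return CommunitySpec("e_surface_like", window, taxa)


def _d_surface_like() -> CommunitySpec:
    window = ObservationWindow.rectangle(0, 0, 9.8, 7.234)  # ≈70.9 m²
    taxa = [
        TaxonSpec("Fractofusus_like", "TC", 1067, {"sigma": 0.15, "rho": 2.5},
                  size_distribution=(0.07, 0.35)),
        TaxonSpec("Pectinifrons_like", "CSR", 108),
        TaxonSpec("Bradgatia_like", "CSR", 140),
    ]
    return CommunitySpec("d_surface_like", window, taxa)


def _bristy_cove_like() -> CommunitySpec:
    window = ObservationWindow.rectangle(0, 0, 0.9, 0.9)  # 0.81 m²
    taxa = [
        TaxonSpec("Fractofusus_like", "TC", 76, {"sigma": 0.03, "rho": 20.0},
                  size_distribution=(0.02, 0.3)),
        TaxonSpec("holdfast_disc", "CSR", 30, group_class="bin_group"),
    ]
    return CommunitySpec("bristy_cove_like", window, taxa)


def _spaniards_bay_like() -> CommunitySpec:
    window = ObservationWindow.rectangle(0, 0, 5.2, 3.154)  # ≈16.4 m²
    taxa = [
        TaxonSpec("Beothukis_like", "HP", 18, {"kind": "gradient_y", "b": 0.5},
                  size_distribution=(0.1, 0.4)),
        TaxonSpec("Trepassia_like", "ITC", 33,
                  {"sigma": 0.12, "rho": 0.4,
                   "surface": {"kind": "gradient_x", "b": 0.5}}),
        TaxonSpec("Avalofractus_like", "CSR", 17),
    ]
    return CommunitySpec("spaniards_bay_like", window, taxa)


# ---------------------------------------------------------------------------
# YAML round-trip
# ---------------------------------------------------------------------------


def spec_to_dict(spec: CommunitySpec) -> dict:
    d: dict = {
        "name": spec.name,
        "window_wkt": spec.window.to_wkt(),
        "seed": spec.seed,
        "taxa": [
            {
                "taxon": t.taxon,
                "process": t.process,
                "target_n": t.target_n,
                "params": t.params,
                "size_distribution": list(t.size_distribution),
                "group_class": t.group_class,
            }
            for t in spec.taxa
        ],
    }
    if spec.strain is not None:
        d["strain"] = {"ratio": spec.strain.ratio, "orientation": spec.strain.orientation}
    if spec.erosion is not None:
        d["erosion"] = {
            "kind": spec.erosion.kind,
            "b": spec.erosion.b,
            "anchor": list(spec.erosion.anchor) if spec.erosion.anchor else None,
        }
    return d


def spec_from_dict(d: dict) -> CommunitySpec:
    strain = None
    if d.get("strain"):
        strain = StrainEstimate(d["strain"]["ratio"], d["strain"]["orientation"])
    erosion = None
    if d.get("erosion"):
        e = d["erosion"]
        erosion = ErosionSpec(e["kind"], e["b"], tuple(e["anchor"]) if e.get("anchor") else None)
    return CommunitySpec(
        name=d["name"],
        window=ObservationWindow.from_wkt(d["window_wkt"]),
        taxa=[
            TaxonSpec(
                taxon=t["taxon"],
                process=t["process"],
                target_n=t["target_n"],
                params=t.get("params", {}),
                size_distribution=tuple(t.get("size_distribution", (0.05, 0.4))),
                group_class=t.get("group_class", "described_taxon"),
            )
            for t in d["taxa"]
        ],
        strain=strain,
        erosion=erosion,
        seed=d.get("seed"),
    )


def save_scenario(spec: CommunitySpec, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(spec_to_dict(spec), sort_keys=False))


def load_scenario(path: str | Path) -> CommunitySpec:
    return spec_from_dict(yaml.safe_load(Path(path).read_text()))
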