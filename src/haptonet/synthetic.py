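"""Synthetic ZOTU tables, metadata and trees with planted ground truth.

The generator emulates a polar-ocean amplicon survey: paired surface /
subsurface-chlorophyll-maximum (SCM) samples at a set of stations, a
log-normal/multinomial count model, a designated set of habitat-enriched
ZOTUs, a temperature gradient driving community dissimilarity, and
block-correlated ZOTU groups that downstream co-occurrence inference is
meant to recover.

Latent model per sample ``s`` and ZOTU ``j``::

    eta[s, j] = base[j]
              + habitat_effect * 1[j enriched in habitat(s)]
              + scm_dominance  * 1[j in dominance set, habitat(s) = SCM]
              + temperature_effect * z_temp[s] * loading[j]
              + noise[s, j]

where ``noise`` has within-block latent correlation ``rho`` (shared factor
with loading sqrt(rho)) and is independent elsewhere.  Counts are a
multinomial draw of size Uniform(depth_range) from ``softmax(eta[s])``.
Everything is driven by one integer seed; identical (design, seed) gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io import METADATA_COLUMNS, ZotuTable

__all__ = [
    "SyntheticDesign",
    "GroundTruth",
    "generate_tree",
    "generate_metadata",
    "generate_counts",
    "DEFAULT_COVARIATE_RANGES",
]

#: per-habitat uniform sampling ranges for the environmental covariates.
#: SCM ranges follow the observed hydrography of a summer Arctic transect
#: (SCM depth 15-62 m, temperature -1.58..2.96 degC, salinity 30.7-32.4,
#: PO4 0.71-2.01 uM, NO2+NO3 0.7-8.22 uM, SiO2 2.55-23.74 uM); surface
#: ranges are warmer, fresher and more oligotrophic.
DEFAULT_COVARIATE_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "surface": {
        "depth": (2.0, 5.0),
        "temperature": (-1.0, 6.0),
        "salinity": (26.0, 31.0),
        "PO4": (0.10, 0.90),
        "NO2NO3": (0.01, 1.50),
        "SiO2": (0.50, 8.00),
        "NH4": (0.05, 0.60),
        "chl_gt20": (0.01, 2.0),
        "chl_2_20": (0.05, 3.0),
        "chl_lt2": (0.05, 2.0),
        "HP_abundance": (1.5e5, 1.2e6),
        "PPE_abundance": (2.0e3, 9.0e3),
    },
    "SCM": {
        "depth": (15.0, 62.0),
        "temperature": (-1.58, 2.96),
        "salinity": (30.7, 32.4),
        "PO4": (0.71, 2.01),
        "NO2NO3": (0.70, 8.22),
        "SiO2": (2.55, 23.74),
        "NH4": (0.05, 0.60),
        "chl_gt20": (0.10, 4.0),
        "chl_2_20": (0.20, 6.66),
        "chl_lt2": (0.10, 3.0),
        "HP_abundance": (1.28e5, 1.01e6),
        "PPE_abundance": (2.12e3, 7.89e3),
    },
}

_GENERA = [
    "Chrysochromulina",
    "Phaeocystis",
    "Prymnesium",
    "Haptolina",
    "Prymnesiophyceae_UC",
    "Clade_HAP3",
    "Clade_B3",
    "Clade_D",
    "Clade_E",
    "Isochrysidales_UC",
]


@dataclass
class SyntheticDesign:
    """Study design and planted-effect sizes for one synthetic dataset.

    ``module_spec`` entries are ``(habitat, member_zotu_ids, rho)`` with
    ``rho`` the within-block latent correlation in [0, 1).  The habitat tag
    records which subnetwork the block is expected to strengthen; the block
    factor itself acts in every sample.  ``n_surface_enriched`` /
    ``n_scm_enriched`` designate how many ZOTUs receive the habitat shift
    (surface-enriched ids come first, then SCM-enriched ones).
    """

    n_stations: int = 14
    layers: tuple[str, str] = ("surface", "SCM")
    n_zotus: int = 300
    depth_range: tuple[int, int] = (35_677, 121_493)
    habitat_effect: float = 0.0
    temperature_effect: float = 0.0
    module_spec: list[tuple[str, list[str], float]] = field(default_factory=list)
    seed: int = 0
    n_surface_enriched: int = 0
    n_scm_enriched: int = 0
    scm_dominance: float = 0.0
    n_dominant: int = 5
    base_sd: float = 1.0
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"surface": 1.0, "SCM": 1.0}
    )
    covariate_ranges: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            h: dict(v) for h, v in DEFAULT_COVARIATE_RANGES.items()
        }
    )

    def __post_init__(self) -> None:
        lo, hi = self.depth_range
        if not (1 <= lo <= hi):
            raise ValueError("depth_range lower bound must be >= 1 and <= upper")
        if self.n_stations < 1 or self.n_zotus < 1:
            raise ValueError("n_stations and n_zotus must be positive")
        if self.habitat_effect < 0 or self.temperature_effect < 0:
            raise ValueError("effect sizes must be nonnegative")
        valid = set(self.zotu_ids())
        seen: dict[str, set[str]] = {}
        for habitat, members, rho in self.module_spec:
            if habitat not in self.layers:
                raise ValueError(f"module habitat {habitat!r} not a layer")
            if not 0 <= rho < 1:
                raise ValueError("module latent correlation must be in [0, 1)")
            mem = set(members)
            unknown = mem - valid
            if unknown:
                raise ValueError(f"module member ids not among ZOTUs: {sorted(unknown)}")
            if mem & seen.setdefault(habitat, set()):
                raise ValueError(f"module blocks overlap within habitat {habitat!r}")
            seen[habitat] |= mem
        if self.n_surface_enriched + self.n_scm_enriched > self.n_zotus:
            raise ValueError("enriched sets exceed n_zotus")

    @classmethod
    def paper_like(cls, seed: int = 0, **overrides) -> "SyntheticDesign":
        """Study-design defaults: 14 stations x {surface, SCM}.

        Plants every qualitative feature the downstream analysis is meant
        to detect.  Higher latent dispersion in the SCM concentrates each
        SCM sample's reads on fewer taxa, giving the surface higher
        observed richness, Shannon and PD at equal sequencing depth; the
        habitat shift on the two designated differential sets separates
        the communities compositionally; the temperature gradient drives
        community dissimilarity through a random loading vector; and the
        surface differential set shares a strong latent factor (a dense
        surface co-occurrence block) while SCM taxa co-vary only weakly,
        so the surface subnetwork is denser and more attack-robust.
        """
        params = dict(
            n_stations=14,
            n_zotus=600,
            depth_range=(35_677, 121_493),
            base_sd=1.5,
            habitat_effect=2.0,
            temperature_effect=1.0,
            n_surface_enriched=60,
            n_scm_enriched=40,
            noise_sd={"surface": 1.0, "SCM": 2.0},
            module_spec=[
                ("surface", [f"ZOTU_{k}" for k in range(1, 61)], 0.85),
                ("SCM", [f"ZOTU_{k}" for k in range(61, 101)], 0.30),
            ],
            seed=seed,
        )
        params.update(overrides)
        return cls(**params)

    def zotu_ids(self) -> list[str]:
        return [f"ZOTU_{k}" for k in range(1, self.n_zotus + 1)]

    def differential_zotus(self) -> dict[str, list[str]]:
        ids = self.zotu_ids()
        return {
            "surface": ids[: self.n_surface_enriched],
            "SCM": ids[
                self.n_surface_enriched : self.n_surface_enriched + self.n_scm_enriched
            ],
        }


@dataclass
class GroundTruth:
    """Planted structure recorded alongside a generated table."""

    differential_zotus: dict[str, list[str]]
    planted_modules: dict[str, str]
    true_driver: str
    latent: np.ndarray

    def to_json(self) -> dict:
        return {
            "differential_zotus": self.differential_zotus,
            "planted_modules": self.planted_modules,
            "true_driver": self.true_driver,
        }


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------

def generate_tree(
    n_leaves: int, seed: int, mean_branch_length: float = 0.1
) -> TreeNode:
    """Random rooted binary tree by sequential joins.

    Leaves are named ``ZOTU_1 .. ZOTU_n``; every branch length is drawn
    i.i.d. exponential with the given mean, so all lengths are positive.
    The same seed reproduces a byte-identical Newick string.
    """
    if n_leaves < 2:
        raise ValueError("a tree needs at least 2 leaves")
    rng = np.random.default_rng(seed)
    nodes = []
    for k in range(1, n_leaves + 1):
        leaf = TreeNode(name=f"ZOTU_{k}")
        leaf.length = float(rng.exponential(mean_branch_length)) or 1e-9
        nodes.append(leaf)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(children=[left, right])
        parent.length = float(rng.exponential(mean_branch_length)) or 1e-9
        nodes.append(parent)
    root = TreeNode(children=list(nodes))
    root.length = None
    return root


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

def generate_metadata(design: SyntheticDesign) -> pd.DataFrame:
    """Per-sample habitat labels and environmental covariates.

    One surface and one SCM sample per station; covariates are uniform
    within the per-habitat ranges, SCM depth always exceeds surface depth
    (the ranges are disjoint), and NH4 is set missing for most SCM samples
    to mimic below-detection measurements.
    """
    rng = np.random.default_rng(design.seed)
    stations = [f"B{k}" for k in range(1, design.n_stations + 1)]
    lat = rng.uniform(70.0, 80.0, size=design.n_stations)
    lon = rng.uniform(-175.0, -150.0, size=design.n_stations)
    rows = []
    # NH4 detectable at ~1/3 of SCM stations, as in summer Arctic casts
    n_det = max(1, design.n_stations // 3)
    nh4_detect = set(rng.choice(design.n_stations, size=n_det, replace=False))
    for i, st in enumerate(stations):
        for layer in design.layers:
            ranges = design.covariate_ranges[layer]
            row = {
                "sample_id": f"{st}.{layer}",
                "habitat": layer,
                "station": st,
                "latitude": float(lat[i]),
                "longitude": float(lon[i]),
            }
            for var, (lo, hi) in ranges.items():
                row[var] = float(rng.uniform(lo, hi))
            if layer == "SCM" and i not in nh4_detect:
                row["NH4"] = np.nan
            rows.append(row)
    meta = pd.DataFrame(rows).set_index("sample_id")
    order = [c for c in METADATA_COLUMNS if c in meta.columns and c != "sample_id"]
    return meta[order]


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def _taxonomy_strings(design: SyntheticDesign, rng: np.random.Generator) -> list[str]:
    genera = rng.choice(len(_GENERA), size=design.n_zotus)
    return [
        "Eukaryota;Haptophyta;Prymnesiophyceae;" + _GENERA[g] + ";" + zid
        for g, zid in zip(genera, design.zotu_ids())
    ]


def generate_counts(
    design: SyntheticDesign, metadata: pd.DataFrame
) -> tuple[ZotuTable, GroundTruth]:
    """Draw the count table and record the planted ground truth.

    See the module docstring for the latent model.  Raises ``ValueError``
    if metadata does not cover the design's stations/layers.
    """
    expected = design.n_stations * len(design.layers)
    if len(metadata) != expected:
        raise ValueError(
            f"metadata has {len(metadata)} samples, design expects {expected}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 17]))
    n_s, n_z = len(metadata), design.n_zotus
    ids = design.zotu_ids()
    id_index = {z: j for j, z in enumerate(ids)}
    habitats = metadata["habitat"].to_numpy()
    temp = metadata["temperature"].to_numpy(dtype=float)
    z_temp = (temp - temp.mean()) / temp.std(ddof=1)

    base = rng.normal(0.0, design.base_sd, size=n_z)
    loading = rng.normal(0.0, 1.0, size=n_z)
    diff = design.differential_zotus()
    shift = np.zeros((n_s, n_z))
    for habitat, members in diff.items():
        cols = [id_index[z] for z in members]
        shift[np.ix_(habitats == habitat, cols)] += design.habitat_effect
    if design.scm_dominance > 0:
        # a handful of bloom-forming taxa dominate the SCM, lowering its
        # evenness and observed richness
        dom = [id_index[z] for z in diff["SCM"][: design.n_dominant]] or list(
            range(n_z - design.n_dominant, n_z)
        )
        shift[np.ix_(habitats == "SCM", dom)] += design.scm_dominance

    noise = rng.normal(0.0, 1.0, size=(n_s, n_z))
    planted: dict[str, str] = {}
    for b, (habitat, members, rho) in enumerate(design.module_spec):
        cols = [id_index[z] for z in members]
        factor = rng.normal(0.0, 1.0, size=n_s)
        noise[:, cols] = (
            np.sqrt(rho) * factor[:, None] + np.sqrt(1.0 - rho) * noise[:, cols]
        )
        label = f"{habitat}_block_{b}"
        for z in members:
            planted[z] = label
    sd = np.array([design.noise_sd.get(h, 1.0) for h in habitats])
    eta = (
        base[None, :]
        + shift
        + design.temperature_effect * z_temp[:, None] * loading[None, :]
        + sd[:, None] * noise
    )
    prob = np.exp(eta - eta.max(axis=1, keepdims=True))
    prob /= prob.sum(axis=1, keepdims=True)
    lo, hi = design.depth_range
    depths = rng.integers(lo, hi + 1, size=n_s)
    counts = np.vstack(
        [rng.multinomial(depths[s], prob[s]) for s in range(n_s)]
    )
    table = ZotuTable(
        counts=counts,
        sample_ids=list(metadata.index),
        zotu_ids=ids,
        taxonomy=_taxonomy_strings(design, rng),
    )
    truth = GroundTruth(
        differential_zotus=diff,
        planted_modules=planted,
        true_driver="temperature",
        latent=eta,
    )
    return table, truth
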