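"""Synthetic erosion-gradient datasets with known ground truth.

The generator emulates a two-site erosion-gradient field design: at each
site, 2 transects x 4 erosion levels (E0/EL/EM/EH) x 3 plots = 24 composite
samples.  It produces

* a soil table whose 13 variables start at site-specific baseline means at
  E0 and decline multiplicatively toward EH (pH near-constant), with
  lognormal multiplicative noise — the default baselines and decline
  ratios follow the magnitudes measured on a loess (sandy-loam) and a
  black-soil (clay-loam) erosion gradient;
* an OTU count table built from a lognormal rank species-abundance
  distribution: erosion removes the rarest fraction of the background pool
  and steepens the abundance distribution (lower richness and evenness),
  while ``n_blocks`` correlated guilds of OTUs share a latent factor
  (within-guild correlation ``block_rho``, hub OTUs loading strongest) and
  decline in abundance with erosion; counts are multinomial draws at a
  lognormally varying sequencing depth;
* the design metadata and a ground-truth record (guild memberships, hubs,
  per-level soil means) for validating downstream inference.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import EROSION_LEVELS, SOIL_VARIABLES, OtuTable, validate_metadata, validate_soil

__all__ = [
    "SimulationConfig",
    "ConfigurationError",
    "SyntheticBundle",
    "generate_soil_table",
    "generate_otu_table",
    "generate_metadata",
    "generate_dataset",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


# E0 baseline means per site archetype (units as in SOIL_VARIABLES docs).
_BASELINE_LOESS: dict[str, float] = {
    "moisture": 21.9, "pH": 8.19, "OC": 7.5, "TN": 0.72, "TP": 0.25,
    "NH4": 4.78, "NO3": 1.78, "AP": 1.88, "AK": 110.7, "MBC": 91.1,
    "MBN": 3.7, "Cm": 3.9, "Nm": 2.9,
}
_BASELINE_BLACKSOIL: dict[str, float] = {
    "moisture": 28.4, "pH": 5.74, "OC": 26.0, "TN": 1.97, "TP": 0.35,
    "NH4": 7.15, "NO3": 2.38, "AP": 27.10, "AK": 175.8, "MBC": 188.1,
    "MBN": 16.3, "Cm": 3.8, "Nm": 21.3,
}

# EH/E0 multiplicative decline ratios per site archetype.  Ratios observed
# above 1 (slight, non-significant increases) are clipped to 1.0 so the
# default gradient is a monotone decline; pH is held constant.
_DECLINE_LOESS: dict[str, float] = {
    "moisture": 0.95, "pH": 1.0, "OC": 0.63, "TN": 0.63, "TP": 1.0,
    "NH4": 0.96, "NO3": 0.66, "AP": 0.90, "AK": 0.92, "MBC": 0.19,
    "MBN": 0.24, "Cm": 1.0, "Nm": 0.59,
}
_DECLINE_BLACKSOIL: dict[str, float] = {
    "moisture": 0.30, "pH": 1.0, "OC": 0.32, "TN": 0.33, "TP": 0.34,
    "NH4": 0.82, "NO3": 0.49, "AP": 0.99, "AK": 0.70, "MBC": 0.17,
    "MBN": 0.78, "Cm": 0.76, "Nm": 0.22,
}

# Coefficients of variation derived from the reported standard errors
# (sd = SE * sqrt(6) at n = 6 plots per level).
_SOIL_CV: dict[str, float] = {
    "moisture": 0.09, "pH": 0.005, "OC": 0.15, "TN": 0.15, "TP": 0.15,
    "NH4": 0.30, "NO3": 0.35, "AP": 0.30, "AK": 0.12, "MBC": 0.35,
    "MBN": 0.40, "Cm": 0.12, "Nm": 0.45,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic erosion-gradient study.

    The defaults reproduce the field design the pipeline targets:
    2 sites x 4 erosion levels x 2 transects x 3 plots (24 samples per
    site), ~20k reads per sample with lognormally uneven depths, 150 OTUs
    with 4 correlated guilds of 10 OTUs (2 hubs each), a 30% effective-
    richness decline and guild abundances falling 8-fold from E0 to EH.
    """

    n_sites: int = 2
    n_erosion_levels: int = 4
    n_transects: int = 2
    n_plots: int = 3
    sequencing_depth: float = 20_000.0
    depth_cv: float = 0.35
    n_otus: int = 150
    diversity_decline: float = 0.3
    mf_decline: Mapping[str, Mapping[str, float]] | Mapping[str, float] | None = None
    n_blocks: int = 4
    block_size: int = 10
    block_rho: float = 0.8
    n_hubs: int = 2
    block_decline: float = 8.0
    block_rel_abundance: float = 4e-4
    sad_sigma: float = 1.0
    latent_sigma: float = 0.6
    soil_cv_scale: float = 1.0
    allow_increase: bool = False
    site_names: tuple[str, ...] | None = None
    soil_baselines: Mapping[str, Mapping[str, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_sites", "n_erosion_levels", "n_transects", "n_plots",
                     "n_otus", "n_blocks", "block_size", "n_hubs"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_erosion_levels > len(EROSION_LEVELS):
            raise ConfigurationError(
                f"at most {len(EROSION_LEVELS)} erosion levels supported"
            )
        if not 0 <= self.diversity_decline < 1:
            raise ConfigurationError("diversity_decline must lie in [0, 1)")
        if not 0 <= self.block_rho < 1:
            raise ConfigurationError("block_rho must lie in [0, 1)")
        if self.n_hubs > self.block_size:
            raise ConfigurationError("n_hubs cannot exceed block_size")
        if self.n_hubs * self.n_blocks > self.n_otus:
            raise ConfigurationError("n_hubs * n_blocks exceeds n_otus")
        if self.n_blocks * self.block_size > self.n_otus:
            raise ConfigurationError("guilds would exceed the OTU pool")
        if self.block_decline < 1 and not self.allow_increase:
            raise ConfigurationError(
                "block_decline < 1 means guild abundance increases with "
                "erosion; set allow_increase=True if intended"
            )
        for site, declines in self._decline_map().items():
            for var, f in declines.items():
                if f <= 0:
                    raise ConfigurationError(f"decline factor {var}={f} must be > 0")
                if f > 1 and not self.allow_increase:
                    raise ConfigurationError(
                        f"decline factor {var}={f} at {site} implies an increase "
                        "from E0 to EH; set allow_increase=True if intended"
                    )

    # -- derived layout -----------------------------------------------------

    @property
    def erosion_labels(self) -> tuple[str, ...]:
        return EROSION_LEVELS[: self.n_erosion_levels]

    @property
    def sites(self) -> tuple[str, ...]:
        if self.site_names is not None:
            if len(self.site_names) != self.n_sites:
                raise ConfigurationError("site_names length must equal n_sites")
            return tuple(self.site_names)
        if self.n_sites == 2:
            return ("loess", "blacksoil")
        return tuple(f"site{i + 1}" for i in range(self.n_sites))

    @property
    def samples_per_site(self) -> int:
        return self.n_erosion_levels * self.n_transects * self.n_plots

    @staticmethod
    def _by_archetype(site: str, i: int, loess: dict, blacksoil: dict) -> dict:
        named = {"loess": loess, "blacksoil": blacksoil}
        return dict(named.get(site, [loess, blacksoil][i % 2]))

    def _baseline_map(self) -> dict[str, dict[str, float]]:
        if self.soil_baselines is not None:
            return {s: dict(self.soil_baselines[s]) for s in self.sites}
        return {
            s: self._by_archetype(s, i, _BASELINE_LOESS, _BASELINE_BLACKSOIL)
            for i, s in enumerate(self.sites)
        }

    def _decline_map(self) -> dict[str, dict[str, float]]:
        sites = self.sites
        if self.mf_decline is None:
            return {
                s: self._by_archetype(s, i, _DECLINE_LOESS, _DECLINE_BLACKSOIL)
                for i, s in enumerate(sites)
            }
        first = next(iter(self.mf_decline.values()))
        if isinstance(first, Mapping):  # per-site mapping
            return {s: dict(self.mf_decline[s]) for s in sites}
        shared = {v: float(f) for v, f in self.mf_decline.items()}
        return {s: dict(shared) for s in sites}


def block_correlation_matrix(
    n_otus: int = 60,
    n_blocks: int = 6,
    block_size: int = 10,
    block_rho_range: tuple[float, float] = (0.82, 0.98),
    noise_bound: float = 0.40,
    dense_noise_fraction: float = 0.4,
    seed: int = 0,
) -> np.ndarray:
    """Symmetric correlation-like matrix with signal blocks over bounded noise.

    Within-block correlations are drawn uniformly from ``block_rho_range``;
    off-block entries are noise with |rho| <= ``noise_bound``: a fraction
    ``dense_noise_fraction`` sits exactly at the bound (random sign) and the
    rest is uniform below 0.95 x bound.  The construction has a known
    separation — the noise support ends at ``noise_bound`` while the signal
    starts near ``block_rho_range[0]`` — so a correlation-threshold
    selection procedure should land strictly between the two.
    """
    if n_blocks * block_size > n_otus:
        raise ConfigurationError("blocks exceed the matrix size")
    rng = np.random.default_rng(seed)
    a = np.zeros((n_otus, n_otus))
    iu = np.triu_indices(n_otus, k=1)
    n_pairs = len(iu[0])
    at_bound = rng.random(n_pairs) < dense_noise_fraction
    mag = np.where(
        at_bound,
        noise_bound,
        rng.uniform(0.0, 0.95 * noise_bound, n_pairs),
    )
    a[iu] = mag * rng.choice([-1.0, 1.0], n_pairs)
    a = a + a.T
    lo, hi = block_rho_range
    idx = 0
    for _ in range(n_blocks):
        members = np.arange(idx, idx + block_size)
        sub = rng.uniform(lo, hi, (block_size, block_size))
        sub = (sub + sub.T) / 2.0
        a[np.ix_(members, members)] = sub
        idx += block_size
    np.fill_diagonal(a, 1.0)
    return a


@dataclass(frozen=True)
class SyntheticBundle:
    """A generated dataset plus the ground truth imposed on it."""

    otu_table: OtuTable
    metadata: pd.DataFrame
    soil_table: pd.DataFrame
    truth: dict


def _sample_layout(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for site in config.sites:
        for level in config.erosion_labels:
            for t in range(1, config.n_transects + 1):
                for p in range(1, config.n_plots + 1):
                    rows.append({
                        "sample_id": f"{site}_{level}_T{t}_P{p}",
                        "site": site,
                        "erosion": level,
                        "transect": f"T{t}",
                        "plot": f"P{p}",
                    })
    return pd.DataFrame(rows)


def generate_metadata(config: SimulationConfig) -> pd.DataFrame:
    """Design metadata: sample_id, site, erosion, transect, plot."""
    return validate_metadata(_sample_layout(config))


def generate_soil_table(config: SimulationConfig) -> pd.DataFrame:
    """Soil variables per plot with erosion-dependent multiplicative decline.

    The mean of variable v at level index l (0-based, L levels) is
    ``baseline[v] * decline[v] ** (l / (L - 1))`` — a geometric
    interpolation from the E0 baseline to the EH endpoint — with
    mean-preserving lognormal noise at the variable's coefficient of
    variation (scaled by ``soil_cv_scale``; 0 disables noise).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    layout = _sample_layout(config)
    baselines = config._baseline_map()
    declines = config._decline_map()
    L = config.n_erosion_levels
    level_index = {lab: i for i, lab in enumerate(config.erosion_labels)}
    values: dict[str, list[float]] = {v: [] for v in SOIL_VARIABLES}
    for _, row in layout.iterrows():
        li = level_index[row["erosion"]]
        frac = li / (L - 1) if L > 1 else 0.0
        for v in SOIL_VARIABLES:
            mean = baselines[row["site"]][v] * declines[row["site"]][v] ** frac
            cv = _SOIL_CV[v] * config.soil_cv_scale
            if cv > 0:
                sigma = np.sqrt(np.log1p(cv ** 2))
                noise = np.exp(rng.normal(-sigma ** 2 / 2.0, sigma))
            else:
                noise = 1.0
            values[v].append(mean * noise)
    soil = pd.concat([layout[["sample_id"]], pd.DataFrame(values)], axis=1)
    return validate_soil(soil)


def _latent_base(config: SimulationConfig) -> np.ndarray:
    """Deterministic lognormal-rank log-abundances, most abundant first."""
    s = config.n_otus
    quantiles = (np.arange(s, 0, -1) - 0.5) / s
    return config.sad_sigma * stats.norm.ppf(quantiles)


def generate_otu_table(config: SimulationConfig) -> tuple[OtuTable, dict]:
    """OTU counts for all samples plus the ground-truth record.

    Community model per sample: latent log-abundance = rank-SAD mean
    (erosion steepens the SAD and removes the rarest background OTUs) +
    guild factor (shared within block, hubs loading strongest) +
    independent noise; counts ~ multinomial(softmax, depth) with depth
    lognormal around ``sequencing_depth``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    layout = _sample_layout(config)
    S = config.n_otus
    L = config.n_erosion_levels
    otu_ids = [f"OTU_{i + 1:04d}" for i in range(S)]
    m_base = _latent_base(config)

    # guild membership: blocks drawn from mid-rank OTUs so they are neither
    # dominant nor in the erosion-removed tail
    block_members: dict[str, list[int]] = {}
    hubs: list[int] = []
    start = min(20, S - config.n_blocks * config.block_size)
    idx = start
    for b in range(config.n_blocks):
        members = list(range(idx, idx + config.block_size))
        block_members[f"block{b + 1}"] = members
        hubs.extend(members[: config.n_hubs])
        idx += config.block_size
    is_block = np.zeros(S, dtype=bool)
    for members in block_members.values():
        is_block[members] = True
    block_of = np.full(S, -1)
    for b, members in enumerate(block_members.values()):
        block_of[members] = b
    is_hub = np.zeros(S, dtype=bool)
    is_hub[hubs] = True

    # pin guild OTUs at a common target relative abundance so their
    # erosion decline translates into presence/absence turnover
    z_norm = np.exp(m_base).sum()
    m_block = np.log(config.block_rel_abundance * z_norm)

    load_member = np.sqrt(config.block_rho)
    load_hub = np.sqrt((1.0 + config.block_rho) / 2.0)
    loading = np.where(is_hub, load_hub, load_member)

    # background OTUs removed per level: rarest fraction of non-guild pool
    background = np.where(~is_block)[0]
    bg_by_rarity = background[np.argsort(m_base[background])]  # rarest first

    level_index = {lab: i for i, lab in enumerate(config.erosion_labels)}
    counts = np.zeros((len(layout), S), dtype=np.int64)
    depths = np.empty(len(layout))
    sigma_d = np.sqrt(np.log1p(config.depth_cv ** 2)) if config.depth_cv > 0 else 0.0

    for r, row in layout.iterrows():
        li = level_index[row["erosion"]]
        frac = li / (L - 1) if L > 1 else 0.0
        m = m_base.copy()
        # steepen the SAD (lower evenness) with erosion
        m *= 1.0 + 0.5 * config.diversity_decline * frac
        # guild abundance decline
        m[is_block] = m_block - np.log(config.block_decline) * frac
        # remove the rarest background fraction
        n_remove = int(np.floor(config.diversity_decline * frac * S))
        removed = bg_by_rarity[: min(n_remove, bg_by_rarity.size)]
        active = np.ones(S, dtype=bool)
        active[removed] = False

        z_blocks = rng.normal(size=config.n_blocks)
        eps = rng.normal(size=S)
        x = m.copy()
        in_block = block_of >= 0
        x[in_block] += config.latent_sigma * (
            loading[in_block] * z_blocks[block_of[in_block]]
            + np.sqrt(1.0 - loading[in_block] ** 2) * eps[in_block]
        )
        x[~in_block] += config.latent_sigma * eps[~in_block]

        p = np.zeros(S)
        p[active] = np.exp(x[active] - x[active].max())
        p /= p.sum()
        if sigma_d > 0:
            depth = int(round(config.sequencing_depth
                              * np.exp(rng.normal(-sigma_d ** 2 / 2.0, sigma_d))))
        else:
            depth = int(round(config.sequencing_depth))
        depth = max(depth, 1)
        depths[r] = depth
        counts[r] = rng.multinomial(depth, p)

    table = OtuTable(pd.DataFrame(counts, index=layout["sample_id"].tolist(),
                                  columns=otu_ids))
    truth = {
        "blocks": {b: [otu_ids[i] for i in members]
                   for b, members in block_members.items()},
        "hubs": [otu_ids[i] for i in hubs],
        "block_rho": config.block_rho,
        "block_decline": config.block_decline,
        "diversity_decline": config.diversity_decline,
        "depths": {sid: int(d) for sid, d in zip(layout["sample_id"], depths)},
    }
    return table, truth


def generate_dataset(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SyntheticBundle:
    """Generate the full bundle and optionally write it to ``out_dir``.

    Writes ``otu_table.tsv`` (OTUs as rows), ``metadata.tsv``, ``soil.tsv``
    and ``truth.json``.
    """
    metadata = generate_metadata(config)
    soil = generate_soil_table(config)
    otu, truth = generate_otu_table(config)

    baselines = config._baseline_map()
    declines = config._decline_map()
    L = config.n_erosion_levels
    truth = dict(truth)
    truth["soil_level_means"] = {
        site: {
            level: {
                v: baselines[site][v]
                * declines[site][v] ** (i / (L - 1) if L > 1 else 0.0)
                for v in SOIL_VARIABLES
            }
            for i, level in enumerate(config.erosion_labels)
        }
        for site in config.sites
    }
    truth["config"] = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in dataclasses.asdict(config).items()
        if isinstance(v, (int, float, str, bool, tuple, type(None)))
    }

    bundle = SyntheticBundle(otu_table=otu, metadata=metadata,
                             soil_table=soil, truth=truth)
    if out_dir is not None:
        from . import io

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_otu_table(otu, out / "otu_table.tsv")
        io.write_metadata(metadata, out / "metadata.tsv")
        io.write_soil_table(soil, out / "soil.tsv")
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
    return bundle
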