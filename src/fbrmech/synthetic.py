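"""Seeded generators for every input class the pipeline consumes.

``simulate_panel_counts`` emulates a two-group biomarker count panel
(negative binomial, variance mu + phi mu^2, lognormal library-size factors,
a planted fraction of genes carrying a log2 fold change between groups).
``simulate_umi_matrix`` emulates a droplet scRNA-seq UMI matrix with two or
more cell populations, library-size variation, a configurable mitochondrial
count fraction, and one signature-high population enriched in one sample
condition.  ``preset_domains`` loads the species-scale mechanical domain
presets (mouse standard implant, mouse vibrating implant, human breast
implant, human titanium implant) from packaged TOML configuration.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from fbrmech.geometry import DomainSpec, ImplantSpec, Layer, MaterialSpec
from fbrmech.loads import LoadSpec
from fbrmech.panel_de import CountMatrix
from fbrmech.sc import UMIMatrix

__all__ = [
    "PanelTruth",
    "ScTruth",
    "simulate_panel_counts",
    "simulate_umi_matrix",
    "preset_domains",
    "PRESET_NAMES",
]

PRESET_NAMES = ("mouse_standard", "mouse_msi", "human_breast", "human_titanium")


@dataclass
class PanelTruth:
    """Ground truth of a simulated two-group panel."""

    de_gene_ids: list
    log2_fold_changes: np.ndarray
    dispersion: np.ndarray
    group_sizes: tuple[int, int]


@dataclass
class ScTruth:
    """Ground truth of a simulated UMI matrix."""

    population_labels: pd.Series
    signature_gene_ids: list
    planted_uplift: float
    condition_labels: pd.Series
    mito_gene_ids: list


def _check_positive_int(name: str, value) -> int:
    if not float(value).is_integer() or int(value) <= 0:
        raise ValueError(f"{name} must be a positive integer, got {value!r}")
    return int(value)


def simulate_panel_counts(
    n_genes: int,
    n_per_group: int,
    frac_de: float,
    lfc: float,
    dispersion: float,
    seed: int,
    mean_log_mean: float = 4.0,
    mean_log_sd: float = 1.5,
    libsize_sd: float = 0.2,
) -> tuple[CountMatrix, PanelTruth]:
    """Two-group NB panel with round(frac_de * n_genes) planted DE genes.

    Gene baseline means are lognormal (median ~ exp(mean_log_mean) counts,
    a placeholder for the panel's unpublished depth profile); sample
    library factors are lognormal(0, libsize_sd).  Planted genes multiply
    the group-2 mean by 2**lfc.  Deterministic in (parameters, seed).
    """
    n_genes = _check_positive_int("n_genes", n_genes)
    n_per_group = _check_positive_int("n_per_group", n_per_group)
    if not (0.0 <= frac_de <= 1.0):
        raise ValueError("frac_de must lie in [0, 1]")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")

    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    base = rng.lognormal(mean_log_mean, mean_log_sd, size=n_genes)
    factors = rng.lognormal(0.0, libsize_sd, size=2 * n_per_group)

    n_de = int(round(frac_de * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    de_idx.sort()

    mu = np.tile(base[:, None], (1, 2 * n_per_group))
    mu[de_idx, n_per_group:] *= 2.0**lfc
    mu = mu * factors[None, :]

    if dispersion > 0:
        r = 1.0 / dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)

    samples = [f"A{i:02d}" for i in range(n_per_group)] + [
        f"B{i:02d}" for i in range(n_per_group)
    ]
    group = pd.Series(
        ["group1"] * n_per_group + ["group2"] * n_per_group, index=samples
    )
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples), group=group
    )
    truth = PanelTruth(
        de_gene_ids=[genes[i] for i in de_idx],
        log2_fold_changes=np.full(n_de, float(lfc)),
        dispersion=np.full(n_genes, float(dispersion)),
        group_sizes=(n_per_group, n_per_group),
    )
    return cm, truth


def simulate_umi_matrix(
    n_cells_per_pop: Sequence[int],
    n_genes: int,
    signature_size: int,
    planted_uplift: float,
    mito_frac_range: tuple[float, float],
    seed: int,
    n_mito_genes: int = 13,
    mean_library: float = 2500.0,
    library_sd: float = 0.35,
    marker_frac: float = 0.05,
    marker_uplift: float = 1.5,
    enriched_condition_prob: float = 0.8,
    background_condition_prob: float = 0.45,
) -> tuple[UMIMatrix, ScTruth]:
    """Sparse UMI matrix with planted populations and a signature-high pop.

    Population 0 expresses the ``signature_size`` signature genes with a
    multiplicative uplift exp(planted_uplift) on the expected expression
    and is preferentially assigned the "MSI" condition (probability
    ``enriched_condition_prob`` vs ``background_condition_prob`` for other
    populations, which get "SM" otherwise).  Every population additionally
    carries its own random marker genes (fraction ``marker_frac``, natural-
    log uplift ``marker_uplift``) so populations are separable beyond the
    planted signature.  Per-cell mitochondrial fractions are uniform on
    ``mito_frac_range``; library sizes are lognormal around
    ``mean_library``.  Counts are Poisson around the cell's expected
    profile (library-size mixing makes the marginal overdispersed).
    """
    n_pops = len(n_cells_per_pop)
    if n_pops < 1:
        raise ValueError("need at least one population")
    sizes = [_check_positive_int("n_cells_per_pop", n) for n in n_cells_per_pop]
    n_genes = _check_positive_int("n_genes", n_genes)
    lo, hi = mito_frac_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("mito_frac_range must be an interval within [0, 1]")
    if planted_uplift < 0:
        raise ValueError("planted_uplift must be >= 0 (downshift not modelled)")
    if signature_size > n_genes - n_mito_genes:
        raise ValueError("signature_size too large for the gene universe")

    rng = np.random.default_rng(seed)
    n_nonmito = n_genes - n_mito_genes
    gene_ids = [f"Gene{i:05d}" for i in range(n_nonmito)] + [
        f"mt-Nd{i}" for i in range(n_mito_genes)
    ]
    mito_ids = gene_ids[n_nonmito:]
    sig_ids = gene_ids[:signature_size]

    base = rng.lognormal(0.0, 1.0, size=n_nonmito)
    pop_profiles = []
    for p in range(n_pops):
        prof = base.copy()
        n_markers = max(1, int(round(marker_frac * n_nonmito)))
        markers = rng.choice(n_nonmito, size=n_markers, replace=False)
        prof[markers] *= np.exp(marker_uplift)
        if p == 0:
            prof[:signature_size] = prof[:signature_size] * np.exp(planted_uplift)
        pop_profiles.append(prof / prof.sum())
    mito_profile = rng.lognormal(0.0, 0.5, size=n_mito_genes)
    mito_profile /= mito_profile.sum()

    blocks, pops, conds = [], [], []
    for p, size in enumerate(sizes):
        lib = rng.lognormal(np.log(mean_library), library_sd, size=size)
        mf = rng.uniform(lo, hi, size=size)
        expected = np.empty((size, n_genes))
        expected[:, :n_nonmito] = np.outer(lib * (1 - mf), pop_profiles[p])
        expected[:, n_nonmito:] = np.outer(lib * mf, mito_profile)
        blocks.append(sp.csr_matrix(rng.poisson(expected)))
        pops.extend([f"pop{p}"] * size)
        p_msi = enriched_condition_prob if p == 0 else background_condition_prob
        conds.extend(
            np.where(rng.random(size) < p_msi, "MSI", "SM").tolist()
        )

    counts = sp.vstack(blocks).tocsr()
    cell_ids = pd.Index([f"cell{i:05d}" for i in range(counts.shape[0])])
    meta = pd.DataFrame(
        {"condition": conds, "population": pops}, index=cell_ids
    )
    umi = UMIMatrix(
        counts=counts,
        cell_ids=cell_ids,
        gene_ids=pd.Index(gene_ids),
        cell_metadata=meta,
        mito_gene_ids=mito_ids,
    )
    truth = ScTruth(
        population_labels=meta["population"],
        signature_gene_ids=list(sig_ids),
        planted_uplift=float(planted_uplift),
        condition_labels=meta["condition"],
        mito_gene_ids=list(mito_ids),
    )
    return umi, truth


def _material(d: dict) -> MaterialSpec:
    return MaterialSpec(
        name=d["name"],
        youngs_modulus=float(d["youngs_modulus_pa"]),
        poisson_ratio=float(d["poisson_ratio"]),
        density=float(d.get("density_kg_m3", 1000.0)),
    )


def domain_from_config(cfg: dict) -> DomainSpec:
    """Build a DomainSpec from a parsed preset/user configuration dict."""
    layers = [
        Layer(
            name=ld["name"],
            thickness=float(ld["thickness_mm"]),
            material=_material(ld["material"]),
        )
        for ld in cfg["layers"]
    ]
    imp = cfg.get("implant")
    implant = None
    if imp is not None:
        implant = ImplantSpec(
            radius=float(imp["radius_mm"]),
            height=float(imp["height_mm"]),
            material=_material(imp["material"]),
            motor_mass=float(imp.get("motor_mass_kg", 0.0)),
        )
    lc = cfg["load"]
    load = LoadSpec(
        kind=lc["kind"],
        magnitude=float(lc.get("magnitude", 0.0)),
        direction=tuple(lc.get("direction", (1.0, 0.0, 0.0))),
        amplitude_g=lc.get("amplitude_g"),
        frequency_hz=lc.get("frequency_hz"),
    )
    return DomainSpec(
        layers=layers,
        lateral_extent=float(cfg["lateral_extent_mm"]),
        load=load,
        implant=implant,
        implant_layer=cfg.get("implant_layer"),
        name=cfg.get("name", "domain"),
    )


def preset_domains(preset: str, **overrides) -> DomainSpec:
    """Load one of the packaged species/implant presets as a DomainSpec.

    Presets: mouse_standard, mouse_msi, human_breast, human_titanium.
    Default moduli, thicknesses and loads live in the TOML files with their
    provenance documented in comments; keyword overrides replace top-level
    config keys before construction.
    """
    if preset not in PRESET_NAMES:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESET_NAMES}")
    text = (
        resources.files("fbrmech").joinpath(f"presets/{preset}.toml").read_text()
    )
    cfg = tomllib.loads(text)
    cfg.update(overrides)
    return domain_from_config(cfg)
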