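"""Pseudo-bulk mixture simulation with known composition and spiked effects.

Two generators live here.  ``make_fixture_reference`` fabricates a
clustered single-nucleus reference — several cardiac-like cell types
with planted type-exclusive marker genes, multiple subjects, per-type
RNA content — so the whole pipeline is buildable without any deposited
data.  ``simulate_experiment`` then mixes per-type expression profiles
at controlled proportions and draws multinomial reads, producing bulk
samples whose composition and differential-expression truth are known.

The benchmark design follows the sweep idea: the major cell type
(cardiomyocytes) runs over a grid of proportions around a 50% baseline,
fibroblasts and macrophages absorb the change in anti-correlation, and
a fixed 10% of genes receive log-normal fold changes (mean log2FC 0.58
~= log2 1.5, sd 0.5) in every non-baseline condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .refbuild import ClusteredReference

__all__ = [
    "CELL_TYPES",
    "MixtureDesign",
    "SimTruth",
    "make_grid",
    "make_fixture_reference",
    "cluster_profile",
    "design_sweep",
    "perturb_proportions",
    "spike_fold_changes",
    "sample_bulk",
    "simulate_experiment",
]

CELL_TYPES = ("cardiomyocyte", "endothelial", "fibroblast", "macrophage",
              "pericyte_smc")

#: Baseline RNA-fraction composition used by the sweep (major type 50%).
BASELINE_PROPORTIONS = {
    "cardiomyocyte": 0.50,
    "endothelial": 0.22,
    "fibroblast": 0.14,
    "macrophage": 0.08,
    "pericyte_smc": 0.06,
}


def make_grid(lo: float, hi: float, step: float) -> np.ndarray:
    """Evenly spaced proportion grid; errors if step does not divide the range."""
    n = (hi - lo) / step
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"step {step} does not divide the range [{lo}, {hi}]")
    return np.round(lo + step * np.arange(round(n) + 1), 10)


@dataclass
class MixtureDesign:
    """Configuration of the mixture sweep.

    cm_grid : grid of major-cell-type (cardiomyocyte) proportions,
        default 0.30..0.70 in steps of 0.005 (81 conditions).
    baseline_cm : the control condition; all contrasts are vs this point.
    n_replicates : samples per condition (unreported upstream; default 4).
    total_reads : multinomial reads per sample.  Desk default 1e5; the
        full-scale figure is 25e6.
    anticorr_split : share of the cardiomyocyte change absorbed by each
        anti-correlated minor type; must sum to 1.
    noise_sd : additive Gaussian jitter on target proportions.
    spike_fraction : fraction of genes receiving a true fold change.
    spike_mu_log2 / spike_sd_log2 : log-normal fold-change parameters on
        the log2 scale (0.58 ~= log2 1.5).
    spike_mode : "lognormal" draws z ~ N(mu, sd); "double" fixes z = 1.
    """

    cm_grid: np.ndarray = field(default_factory=lambda: make_grid(0.30, 0.70, 0.005))
    baseline_cm: float = 0.50
    n_replicates: int = 4
    total_reads: int = 100_000
    anticorr_split: dict = field(
        default_factory=lambda: {"fibroblast": 0.6, "macrophage": 0.4})
    noise_sd: float = 0.005
    spike_fraction: float = 0.10
    spike_mu_log2: float = 0.58
    spike_sd_log2: float = 0.5
    spike_mode: str = "lognormal"
    baseline_proportions: dict = field(
        default_factory=lambda: dict(BASELINE_PROPORTIONS))
    seed: int = 0

    def __post_init__(self) -> None:
        self.cm_grid = np.asarray(self.cm_grid, dtype=float)
        if ((self.cm_grid <= 0) | (self.cm_grid >= 1)).any():
            raise ValueError("cm_grid values must lie in (0, 1)")
        split = np.array(list(self.anticorr_split.values()), dtype=float)
        if (split < 0).any() or abs(split.sum() - 1.0) > 1e-9:
            raise ValueError("anticorr_split values must be >=0 and sum to 1")
        if not 0 <= self.spike_fraction < 1:
            raise ValueError("spike_fraction must lie in [0, 1)")
        if self.spike_mode not in ("lognormal", "double"):
            raise ValueError("spike_mode must be 'lognormal' or 'double'")
        props = pd.Series(self.baseline_proportions, dtype=float)
        if abs(props.sum() - 1.0) > 1e-9 or (props <= 0).any():
            raise ValueError("baseline_proportions must be positive and sum to 1")
        if abs(props["cardiomyocyte"] - self.baseline_cm) > 1e-9:
            raise ValueError("baseline_proportions must place baseline_cm on "
                             "the cardiomyocyte entry")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cm_grid"] = [float(x) for x in self.cm_grid]
        return d


@dataclass
class SimTruth:
    """Simulated bulk counts together with their generating truth.

    bulk_counts : genes x samples integer DataFrame; every column sums
        to ``total_reads`` exactly.
    true_proportions : samples x cell types, post-noise, rows sum to 1.
    condition : per-sample condition label (the grid cm value).
    spiked_genes : genes carrying a true fold change in all non-baseline
        conditions.
    spiked_log2fc : Series over spiked_genes, the log2 fold change z.
    """

    bulk_counts: pd.DataFrame
    true_proportions: pd.DataFrame
    condition: pd.Series
    spiked_genes: set
    spiked_log2fc: pd.Series
    baseline_label: str
    design: MixtureDesign

    def __post_init__(self) -> None:
        rs = self.true_proportions.sum(axis=1).to_numpy()
        if np.abs(rs - 1.0).max() > 1e-12:
            raise ValueError("true proportions must sum to 1 per sample")
        if set(self.spiked_log2fc.index) != set(self.spiked_genes):
            raise ValueError("spiked_log2fc must be defined exactly on spiked_genes")


def make_fixture_reference(n_genes: int = 2000, n_cell_types: int = 5,
                           n_subjects: int = 3, n_nuclei_per_type: int = 300,
                           marker_frac: float = 0.05, seed: int = 0,
                           marker_boost: float = 12.0,
                           marker_damp: float = 0.1,
                           base_depth: float = 1500.0,
                           return_markers: bool = False):
    """Fabricate a clustered single-nucleus reference with planted markers.

    Per cell type, mean expression is a shared gamma-distributed base
    profile modulated by a log-normal type deviation (sd 1 on the natural
    log scale — cell types genuinely differ).  ``marker_frac`` of genes
    per type are planted as markers: boosted ``marker_boost``-fold in
    their own type and damped to ``marker_damp`` of base elsewhere, so
    the in/out ratio is far above the 8-fold planting floor.  Nucleus
    counts are Poisson around subject- and library-jittered means; types
    carry distinct expected totals so cell-size factors are non-trivial.

    With ``return_markers=True`` also returns the planted truth as a
    ``{cell_type: [gene, ...]}`` map.
    """
    if n_cell_types < 2:
        raise ValueError("need at least 2 cell types")
    rng = np.random.default_rng(seed)
    types = list(CELL_TYPES[:n_cell_types])
    types += [f"type_{i}" for i in range(len(types), n_cell_types)]
    genes = np.array([f"gene{i:05d}" for i in range(n_genes)], dtype=object)

    base = rng.gamma(shape=2.0, scale=1.0, size=n_genes) + 0.05
    dev = rng.lognormal(mean=0.0, sigma=1.0, size=(n_genes, n_cell_types))
    lam = base[:, None] * dev  # genes x types

    n_markers = int(round(marker_frac * n_genes))
    marker_idx = rng.choice(n_genes, size=n_markers * n_cell_types, replace=False)
    for k in range(n_cell_types):
        idx = marker_idx[k * n_markers:(k + 1) * n_markers]
        # markers are well-expressed genes: floor the base so every
        # planted marker separates cleanly from background
        base_m = np.maximum(base[idx], 0.5)
        lam[idx, :] = base_m[:, None] * marker_damp
        lam[idx, k] = base_m * marker_boost

    # relative RNA content per type; cardiomyocytes are large cells
    type_size = np.linspace(1.0, 0.7, n_cell_types)
    if n_cell_types >= 1:
        type_size[0] = 2.5
    lam = lam / lam.sum(axis=0, keepdims=True) * base_depth * type_size[None, :]

    counts_cols, meta_rows = [], []
    subjects = [f"subject{j + 1}" for j in range(n_subjects)]
    per_subject = np.full(n_subjects, n_nuclei_per_type // n_subjects)
    per_subject[: n_nuclei_per_type % n_subjects] += 1
    for k, ct in enumerate(types):
        for j, subj in enumerate(subjects):
            n_nuc = int(per_subject[j])
            if n_nuc == 0:
                continue
            subj_jitter = rng.lognormal(0.0, 0.15, size=n_genes)
            lib = rng.lognormal(0.0, 0.3, size=n_nuc)
            rate = (lam[:, k] * subj_jitter)[:, None] * lib[None, :]
            counts_cols.append(sp.csr_matrix(rng.poisson(rate)))
            meta_rows += [(ct, subj)] * n_nuc
    counts = sp.hstack(counts_cols, format="csr")
    meta = pd.DataFrame(meta_rows, columns=["cluster", "subject"])
    meta.index = [f"nucleus{i:05d}" for i in range(len(meta))]
    reference = ClusteredReference(counts=counts, gene_ids=genes,
                                   nucleus_meta=meta)
    if return_markers:
        planted = {
            ct: sorted(genes[marker_idx[k * n_markers:(k + 1) * n_markers]])
            for k, ct in enumerate(types)
        }
        return reference, planted
    return reference


def cluster_profile(reference: ClusteredReference, cell_type) -> pd.Series:
    """Relative expression profile of one cluster.

    Sums counts over all nuclei of the cluster and normalizes by the
    total, yielding the probability that a read sampled from this cell
    type comes from each gene.
    """
    mask = (reference.nucleus_meta["cluster"] == cell_type).to_numpy()
    if not mask.any():
        raise ValueError(f"cell type {cell_type!r} has no nuclei")
    sums = np.asarray(reference.counts[:, mask].sum(axis=1)).ravel().astype(float)
    total = sums.sum()
    if total <= 0:
        raise ValueError(f"cell type {cell_type!r} has zero total counts")
    return pd.Series(sums / total, index=reference.gene_ids, name=cell_type)


def design_sweep(design: MixtureDesign) -> list:
    """Expand the design grid into condition cm values (baseline included).

    The baseline point must lie on the grid; every later contrast is
    condition vs baseline.
    """
    grid = design.cm_grid
    if not np.any(np.abs(grid - design.baseline_cm) < 1e-9):
        raise ValueError(
            f"baseline {design.baseline_cm} is not on the grid "
            f"[{grid.min()}, {grid.max()}]"
        )
    return [float(x) for x in grid]


def perturb_proportions(cm_target: float, design: MixtureDesign,
                        baseline_props: pd.Series, rng) -> pd.Series:
    """Target composition for one sample at a given cardiomyocyte level.

    The cardiomyocyte change relative to baseline is absorbed by the
    anti-correlated types per ``anticorr_split``; the remaining types
    share the residual mass proportionally to their baseline values.
    Gaussian jitter (sd ``noise_sd``) is added, negatives clipped, and
    the vector renormalized to sum 1.
    """
    props = baseline_props.astype(float).copy()
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("baseline_props must sum to 1")
    delta = cm_target - props["cardiomyocyte"]
    props["cardiomyocyte"] = cm_target
    for ct, share in design.anticorr_split.items():
        props[ct] -= delta * share
    others = [ct for ct in props.index
              if ct != "cardiomyocyte" and ct not in design.anticorr_split]
    if others:
        residual = 1.0 - props.drop(others).sum()
        base_other = baseline_props[others]
        props[others] = base_other / base_other.sum() * residual
    if design.noise_sd > 0:
        props += rng.normal(0.0, design.noise_sd, size=len(props))
    if (props < -0.05).any():
        warnings.warn("target proportions pushed well below 0; clipping",
                      UserWarning)
    props = props.clip(lower=0.0)
    return props / props.sum()


def spike_fold_changes(profiles: pd.DataFrame, spiked_genes, design: MixtureDesign,
                       rng) -> tuple:
    """Apply log-normal fold changes to spiked genes in every type profile.

    Per spiked gene a single z (log2 fold change) is drawn — N(0.58,
    0.5) in "lognormal" mode, exactly 1 in "double" mode — and the
    gene's probability mass is multiplied by 2**z in every cell-type
    profile, after which each profile is renormalized to sum 1.

    Returns (perturbed profiles, Series of z over spiked genes).
    """
    spiked = list(spiked_genes)
    missing = set(spiked) - set(profiles.index)
    if missing:
        raise ValueError(f"spiked genes outside the universe: {sorted(missing)[:5]}")
    if design.spike_mode == "double":
        z = np.ones(len(spiked))
    else:
        z = rng.normal(design.spike_mu_log2, design.spike_sd_log2, size=len(spiked))
    z = pd.Series(z, index=pd.Index(spiked, name="gene"), name="log2fc")
    out = profiles.copy()
    if spiked:
        out.loc[spiked] = out.loc[spiked].mul(2.0 ** z, axis=0)
        out = out / out.sum(axis=0)
    return out, z


def sample_bulk(profile_mixture: np.ndarray, total_reads: int, rng) -> np.ndarray:
    """One multinomial draw of ``total_reads`` reads from a mixed profile."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    pi = np.asarray(profile_mixture, dtype=float)
    if (pi < 0).any():
        raise ValueError("profile mixture must be non-negative")
    return rng.multinomial(int(total_reads), pi / pi.sum())


def simulate_experiment(reference: ClusteredReference, design: MixtureDesign,
                        conditions=None) -> SimTruth:
    """Generate the full pseudo-bulk experiment for a set of conditions.

    ``conditions`` defaults to the whole grid from :func:`design_sweep`.
    Per condition and replicate: draw target proportions, mix the
    per-type profiles (spiked profiles for non-baseline conditions) and
    sample ``total_reads`` reads multinomially.  Fully reproducible from
    ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    if conditions is None:
        conditions = design_sweep(design)
    conditions = [float(c) for c in conditions]
    if not any(abs(c - design.baseline_cm) < 1e-9 for c in conditions):
        raise ValueError("conditions must include the baseline point")

    baseline_props = pd.Series(design.baseline_proportions, dtype=float)
    missing = set(baseline_props.index) - set(reference.cell_types)
    if missing:
        raise ValueError(f"reference lacks cell types {sorted(missing)}")
    profiles = pd.concat(
        [cluster_profile(reference, ct) for ct in baseline_props.index], axis=1)

    n_spiked = int(round(design.spike_fraction * reference.n_genes))
    spiked = rng.choice(reference.gene_ids, size=n_spiked, replace=False)
    spiked_profiles, z = spike_fold_changes(profiles, list(spiked), design, rng)

    counts_cols, prop_rows, labels, ids = [], [], [], []
    for cm in conditions:
        is_baseline = abs(cm - design.baseline_cm) < 1e-9
        prof = profiles if is_baseline else spiked_profiles
        label = f"cm{cm:.3f}"
        for r in range(design.n_replicates):
            props = perturb_proportions(cm, design, baseline_props, rng)
            mixture = prof.to_numpy() @ props.reindex(prof.columns).to_numpy()
            counts_cols.append(sample_bulk(mixture, design.total_reads, rng))
            prop_rows.append(props)
            labels.append(label)
            ids.append(f"{label}_r{r + 1}")

    bulk = pd.DataFrame(np.column_stack(counts_cols), index=profiles.index,
                        columns=ids)
    true_props = pd.DataFrame(prop_rows, index=ids)
    condition = pd.Series(labels, index=ids, name="condition")
    return SimTruth(
        bulk_counts=bulk,
        true_proportions=true_props,
        condition=condition,
        spiked_genes=set(spiked.tolist()),
        spiked_log2fc=z,
        baseline_label=f"cm{design.baseline_cm:.3f}",
        design=design,
    )
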