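"""Synthetic IMHA cohort generator.

Forward model for every downstream stage, with known ground truth:

* CBCs are drawn log-normally around group means.  Case means mirror the
  hematology of immune-mediated hemolytic anemia relative to controls —
  neutrophils x2.5, reticulocytes x6, RBCs x0.45, monocytes x2,
  platelets x0.7, lymphocytes and eosinophils unchanged.
* Whole-blood expression is a CBC-weighted mixture of per-cell-type
  signatures using the composition model's RNA-mass constants (including
  globin depletion), with planted differentially expressed genes,
  latent-trait-driven gene modules, and negative-binomial noise
  (variance mu + alpha*mu^2).
* Taxa counts, and triplicate qPCR Ct tables with known fold changes,
  give the stability-selection and ddCT stages a truth-bearing test bed.

Everything is deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import composition as comp
from .composition import CELL_TYPES, CBCRecord, CellTypeRNAProfile
from .io import CountMatrix


class SpecError(ValueError):
    """Invalid cohort specification."""


#: Control-group CBC means (cells per uL), canine reference-interval
#: midpoints, and the case/control mean ratios emulating IMHA.
CONTROL_CBC_MEANS = {
    "neutrophil": 4.8e3,
    "monocyte": 4.0e2,
    "lymphocyte": 2.0e3,
    "eosinophil": 3.0e2,
    "rbc": 6.5e6,
    "platelet": 3.0e5,
    "reticulocyte": 5.0e4,
}
CASE_RATIOS = {
    "neutrophil": 2.5,
    "monocyte": 2.0,
    "lymphocyte": 1.0,
    "eosinophil": 1.0,
    "rbc": 0.45,
    "platelet": 0.7,
    "reticulocyte": 6.0,
}
CBC_CVS = {
    "neutrophil": 0.35,
    "monocyte": 0.40,
    "lymphocyte": 0.35,
    "eosinophil": 0.50,
    "rbc": 0.15,
    "platelet": 0.30,
    "reticulocyte": 0.50,
}


@dataclass
class ModuleSpec:
    """A planted co-expression block driven by a latent trait.

    Member genes share a per-dog multiplier 2^(amplitude * z), where z is
    a module latent correlated (at ``rho``) with the standardized log of
    the driving cell count.
    """

    genes: list
    trait: str  # one of CELL_TYPES
    rho: float = 0.9
    amplitude: float = 1.0


@dataclass
class QPCRSpec:
    """True fold changes (case vs control) and Ct noise for the qPCR bed."""

    target_folds: dict = field(
        default_factory=lambda: {"TGT_A": 0.25, "TGT_B": 0.5}
    )
    housekeeping: list = field(default_factory=lambda: ["HK1", "HK2", "HK3"])
    n_cases: int = 6
    n_controls: int = 4
    ct_sd: float = 0.15
    dog_offset_sd: float = 0.3  # RNA-input offset, common to all genes in a dog


@dataclass
class CohortSpec:
    n_cases: int = 18
    n_controls: int = 18
    cbc_means: dict = field(default_factory=dict)  # group -> cell type -> mean
    cbc_cvs: dict = field(default_factory=lambda: dict(CBC_CVS))
    n_genes: int = 2000
    signature: pd.DataFrame | None = None  # gene x cell type, columns sum to 1
    planted_degs: dict = field(default_factory=dict)  # gene -> true log2FC
    module_specs: list = field(default_factory=list)
    nb_dispersion: float = 0.05
    library_size: int = 2_000_000
    gene_length_kb: pd.Series | None = None
    n_taxa: int = 50
    taxa_mean: float = 100.0
    taxa_dispersion: float = 0.5
    planted_taxa: dict = field(default_factory=dict)  # taxon -> case log2 effect
    qpcr: QPCRSpec = field(default_factory=QPCRSpec)
    profile: CellTypeRNAProfile = field(default_factory=CellTypeRNAProfile)

    def __post_init__(self):
        if not self.cbc_means:
            self.cbc_means = {
                "control": dict(CONTROL_CBC_MEANS),
                "case": {
                    ct: CONTROL_CBC_MEANS[ct] * CASE_RATIOS[ct] for ct in CELL_TYPES
                },
            }
        for group, means in self.cbc_means.items():
            for ct, m in means.items():
                if m <= 0:
                    raise SpecError(f"non-positive CBC mean for {group}/{ct}")
        if self.nb_dispersion < 0 or self.taxa_dispersion < 0:
            raise SpecError("dispersions must be >= 0")
        if self.library_size <= 0:
            raise SpecError("library_size must be > 0")


def gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def default_signature(
    n_genes: int, seed: int = 7, frac_exclusive: float = 0.30
) -> pd.DataFrame:
    """Gene x cell-type expression weights, columns normalized to sum 1.

    ~30% of genes are exclusive to one cell type (these carry the pure
    composition signal); the rest mix across cell types with Dirichlet
    weights.  Per-gene base abundance is log-normal.
    """
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=0.0, sigma=1.5, size=n_genes)
    W = np.zeros((n_genes, len(CELL_TYPES)))
    exclusive = rng.random(n_genes) < frac_exclusive
    excl_type = rng.integers(0, len(CELL_TYPES), size=n_genes)
    W[exclusive, excl_type[exclusive]] = 1.0
    n_shared = int((~exclusive).sum())
    W[~exclusive] = rng.dirichlet(np.full(len(CELL_TYPES), 0.3), size=n_shared)
    W = W * base[:, None]
    W = W / W.sum(axis=0, keepdims=True)  # unit RNA mass -> unit expression
    return pd.DataFrame(W, index=gene_names(n_genes), columns=list(CELL_TYPES))


def default_cohort_spec(
    n_cases: int = 18,
    n_controls: int = 18,
    n_genes: int = 2000,
    n_deg: int = 50,
    module_size: int = 150,
    seed: int = 7,
) -> CohortSpec:
    """The default study conditions: planted DEGs at |log2FC| in {2,3,4} on
    broadly expressed genes, plus neutrophil- and reticulocyte-driven
    modules disjoint from the DEG set."""
    rng = np.random.default_rng(seed)
    sig = default_signature(n_genes, seed=seed)
    genes = list(sig.index)
    # broadly expressed genes: no cell type holds > 90% of the weight
    weights = sig.div(sig.sum(axis=1), axis=0)
    broad = weights.max(axis=1) < 0.9
    pool = rng.permutation(np.array(genes)[broad.to_numpy()])
    deg_genes = pool[:n_deg]
    mod_neut = pool[n_deg : n_deg + module_size]
    mod_retic = pool[n_deg + module_size : n_deg + 2 * module_size]
    mags = rng.choice([2.0, 3.0, 4.0], size=n_deg)
    signs = np.where(np.arange(n_deg) % 2 == 0, 1.0, -1.0)
    planted = {g: s * m for g, s, m in zip(deg_genes, signs, mags)}
    modules = [
        ModuleSpec(list(mod_neut), "neutrophil", rho=0.9, amplitude=2.0),
        ModuleSpec(list(mod_retic), "reticulocyte", rho=0.9, amplitude=2.0),
    ]
    lengths = pd.Series(
        rng.integers(300, 10_000, size=n_genes).astype(float), index=genes
    )
    return CohortSpec(
        n_cases=n_cases,
        n_controls=n_controls,
        n_genes=n_genes,
        signature=sig,
        planted_degs=planted,
        module_specs=modules,
        gene_length_kb=lengths,
        planted_taxa={"taxon_00": 2.0, "taxon_01": 3.0},
    )


def simulate_cbc(spec: CohortSpec, seed: int) -> list[CBCRecord]:
    """Draw per-dog CBCs log-normally around the group means.

    With mean m and coefficient of variation cv, sigma^2 = ln(1 + cv^2)
    and mu = ln m - sigma^2/2, so the arithmetic mean is exactly m; cv = 0
    degenerates to the group mean.
    """
    rng = np.random.default_rng(seed)
    records = []
    for group, n in (("case", spec.n_cases), ("control", spec.n_controls)):
        means = spec.cbc_means[group]
        for i in range(n):
            counts = {}
            for ct in CELL_TYPES:
                m, cv = means[ct], spec.cbc_cvs.get(ct, 0.0)
                if cv == 0:
                    counts[ct] = float(m)
                else:
                    s2 = np.log1p(cv**2)
                    counts[ct] = float(
                        rng.lognormal(np.log(m) - s2 / 2, np.sqrt(s2))
                    )
            records.append(
                CBCRecord(dog_id=f"{group}_{i:02d}", group=group, counts=counts)
            )
    return records


def simulate_case_subpopulations(
    spec: CohortSpec, seed: int, neutrophil_ratio: float = 3.0
) -> tuple[list[CBCRecord], pd.Series]:
    """Cohort whose cases split into two subpopulations differing only in
    neutrophil abundance (inflammatory vs quiescent presentations).

    The second half of the cases has its neutrophil mean multiplied by
    ``neutrophil_ratio``.  Returns the CBC records and a case-only Series
    mapping dog_id -> subpopulation label ("low"/"high").
    """
    base = simulate_cbc(spec, seed)
    rng = np.random.default_rng(seed + 9)
    cases = [c for c in base if c.group == "case"]
    subpop = {}
    out = []
    half = len(cases) // 2
    for i, c in enumerate(base):
        if c.group != "case":
            out.append(c)
            continue
        j = cases.index(c)
        if j < half:
            subpop[c.dog_id] = "low"
            out.append(c)
        else:
            subpop[c.dog_id] = "high"
            counts = dict(c.counts)
            m = counts["neutrophil"] * neutrophil_ratio
            cv = spec.cbc_cvs.get("neutrophil", 0.0)
            # redraw around the shifted mean to keep the log-normal shape
            if cv > 0:
                s2 = np.log1p(cv**2)
                m = float(rng.lognormal(np.log(
                    spec.cbc_means["case"]["neutrophil"] * neutrophil_ratio
                ) - s2 / 2, np.sqrt(s2)))
            counts["neutrophil"] = m
            out.append(CBCRecord(c.dog_id, "case", counts))
    return out, pd.Series(subpop, name="subpopulation")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial with variance mu + alpha*mu^2 via gamma-Poisson."""
    if alpha == 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
    return rng.poisson(lam)


def expected_expression(
    cbcs: list[CBCRecord], spec: CohortSpec, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-dog expected counts (before NB noise) and the RNA fractions used.

    Expected count of gene g in dog d is library_size times the normalized
    mixture sum_c fraction_RNA(c, d) * signature(g, c), scaled by 2^log2FC
    for planted DEGs in cases and by the module multipliers.
    """
    if spec.signature is None:
        raise SpecError("spec.signature is required")
    missing = [ct for ct in CELL_TYPES if ct not in spec.signature.columns]
    if missing:
        raise SpecError(f"signature missing cell types {missing}")
    est = comp.estimate_cohort(cbcs, spec.profile)
    frac = est.pivot(index="dog_id", columns="cell_type", values="fraction")
    frac = frac.loc[[c.dog_id for c in cbcs], list(CELL_TYPES)]
    sig = spec.signature[list(CELL_TYPES)]
    W = sig.to_numpy() @ frac.to_numpy().T  # gene x dog
    W = pd.DataFrame(W, index=sig.index, columns=frac.index)

    is_case = np.array([c.group == "case" for c in cbcs], dtype=float)
    for g, l2fc in spec.planted_degs.items():
        if g not in W.index:
            raise SpecError(f"planted DEG {g!r} not in signature")
        W.loc[g] = W.loc[g] * np.power(2.0, l2fc * is_case)

    # module multipliers share a per-dog latent correlated with the trait
    rng = np.random.default_rng(seed)
    counts_by_ct = {
        ct: np.array([c.counts[ct] for c in cbcs]) for ct in CELL_TYPES
    }
    for mod in spec.module_specs:
        logc = np.log(counts_by_ct[mod.trait])
        z_trait = (logc - logc.mean()) / logc.std()
        eps = rng.standard_normal(len(cbcs))
        z = mod.rho * z_trait + np.sqrt(1 - mod.rho**2) * eps
        mult = np.power(2.0, mod.amplitude * z)
        missing = [g for g in mod.genes if g not in W.index]
        if missing:
            raise SpecError(f"module gene {missing[0]!r} not in signature")
        W.loc[mod.genes] = W.loc[mod.genes].to_numpy() * mult[None, :]

    mu = spec.library_size * W / W.sum(axis=0)
    return mu, frac


def simulate_expression(
    cbcs: list[CBCRecord], spec: CohortSpec, seed: int
) -> CountMatrix:
    """Draw the gene x dog count matrix for the cohort."""
    mu, _ = expected_expression(cbcs, spec, seed)
    rng = np.random.default_rng(seed + 1)
    counts = _nb_draw(rng, mu.to_numpy(), spec.nb_dispersion)
    df = pd.DataFrame(counts.astype(np.int64), index=mu.index, columns=mu.columns)
    return CountMatrix(df, gene_lengths=spec.gene_length_kb)


def cohort_metadata(cbcs: list[CBCRecord]) -> pd.DataFrame:
    rows = {
        c.dog_id: {"group": c.group, **{ct: c.counts[ct] for ct in CELL_TYPES}}
        for c in cbcs
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "dog_id"
    return df


def simulate_taxa(
    spec: CohortSpec, labels: pd.Series, seed: int
) -> CountMatrix:
    """Taxa x sample counts: NB background with a shared mean; planted taxa
    have their case-group mean multiplied by 2^effect."""
    taxa = [f"taxon_{i:02d}" for i in range(spec.n_taxa)]
    unknown = set(spec.planted_taxa) - set(taxa)
    if unknown:
        raise SpecError(f"planted effect on unknown taxon {sorted(unknown)[0]!r}")
    rng = np.random.default_rng(seed)
    is_case = (labels == "case").to_numpy(dtype=float)
    mu = np.full((spec.n_taxa, len(labels)), spec.taxa_mean)
    for t, eff in spec.planted_taxa.items():
        i = taxa.index(t)
        mu[i] = mu[i] * np.power(2.0, eff * is_case)
    # per-sample library-depth variation
    depth = rng.lognormal(mean=0.0, sigma=0.3, size=len(labels))
    mu = mu * depth[None, :]
    counts = _nb_draw(rng, mu, spec.taxa_dispersion)
    df = pd.DataFrame(
        counts.astype(np.int64), index=taxa, columns=list(labels.index)
    )
    return CountMatrix(df)


def simulate_qpcr(spec: CohortSpec, seed: int) -> pd.DataFrame:
    """Triplicate Ct table for the qPCR bed.

    Ct = per-gene baseline - log2(relative expression) + Gaussian noise;
    a per-dog offset common to all genes models RNA-input differences and
    cancels in the ddCT.  Housekeeping genes have true fold 1.
    """
    q = spec.qpcr
    rng = np.random.default_rng(seed)
    genes = list(q.target_folds) + list(q.housekeeping)
    baselines = {g: rng.uniform(18.0, 26.0) for g in genes}
    rows = []
    for group, n in (("case", q.n_cases), ("control", q.n_controls)):
        for i in range(n):
            dog = f"q{group}_{i:02d}"
            offset = rng.normal(0.0, q.dog_offset_sd)
            for g in genes:
                fold = q.target_folds.get(g, 1.0)
                log2expr = (np.log2(fold) if group == "case" else 0.0) + offset
                for rep in range(3):
                    ct = baselines[g] - log2expr + rng.normal(0.0, q.ct_sd)
                    rows.append(
                        {
                            "dog_id": dog,
                            "group": group,
                            "gene": g,
                            "replicate": rep + 1,
                            "ct": ct,
                        }
                    )
    return pd.DataFrame(rows)


def truth_tables(spec: CohortSpec) -> dict:
    """Ground-truth tables for planted effects, for recovery scoring."""
    degs = pd.DataFrame(
        {"gene": list(spec.planted_degs), "true_log2fc": list(spec.planted_degs.values())}
    )
    modules = pd.concat(
        [
            pd.DataFrame(
                {"gene": m.genes, "trait": m.trait, "module_index": i}
            )
            for i, m in enumerate(spec.module_specs)
        ],
        ignore_index=True,
    ) if spec.module_specs else pd.DataFrame(columns=["gene", "trait", "module_index"])
    taxa = pd.DataFrame(
        {"taxon": list(spec.planted_taxa), "true_log2_effect": list(spec.planted_taxa.values())}
    )
    qpcr = pd.DataFrame(
        {
            "gene": list(spec.qpcr.target_folds) + list(spec.qpcr.housekeeping),
            "true_fold": list(spec.qpcr.target_folds.values())
            + [1.0] * len(spec.qpcr.housekeeping),
        }
    )
    return {"degs": degs, "modules": modules, "taxa": taxa, "qpcr": qpcr}
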