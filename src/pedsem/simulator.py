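"""Pedigree data simulation: founder haplotypes, gene dropping, SEM traits.

The simulator is the package's own data-generating counterpart to the
fitting pipeline.  Given pedigree structures, a compiled model, and true
parameter values it

1. draws founder haplotypes from a phased panel (a synthetic panel with
   controllable allele frequencies and adjacent-marker LD stands in for
   real phased reference data),
2. gene-drops alleles through each pedigree, tracking founder-haplotype
   descent labels, from which marker-specific true IBD sharing matrices
   are computed,
3. draws each variance component as a matrix-normal deviate with row
   covariance R_c (relationship matrix) and column covariance Psi_c /
   Theta_c, and assembles traits through the structural equations, and
4. optionally applies single-proband ascertainment: a member is affected
   when its mean trait value exceeds the population threshold for a given
   prevalence, affected members become proband candidates with a fixed
   probability, the first candidate is the proband, and pedigrees without
   a proband are discarded.

The whole simulator is a pure function of (configuration, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .model import ModelMatrices, ModelSpec, build_model_matrices, parse_model
from .moments import implied_component_covariance, implied_mean_coefficients
from .pedigree import IbdStore, Individual, Pedigree, kinship_matrix
from .estimation import component_marker

__all__ = [
    "HaplotypePanel",
    "SimulationConfig",
    "SimulatedData",
    "generate_synthetic_panel",
    "gene_drop",
    "true_ibd_matrix",
    "simulate_phenotypes",
    "apply_ascertainment",
    "affection_threshold",
    "preset_pedigrees",
    "replicate_structures",
    "simulate_dataset",
]


# ---------------------------------------------------------------------------
# haplotype panel


@dataclass
class HaplotypePanel:
    """Phased founder haplotypes: marker metadata plus a 0/1 matrix."""

    names: list[str]
    positions: np.ndarray          # bp, strictly increasing
    haplotypes: np.ndarray         # (n_haplotypes, n_markers) of {0, 1}

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.shape[0] < 2:
            raise ConfigurationError("panel needs at least 2 haplotypes")
        if np.any(np.diff(self.positions) <= 0):
            raise ConfigurationError("marker positions must be strictly increasing")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ConfigurationError("panel alleles must be coded 0/1")

    @property
    def n_markers(self) -> int:
        return len(self.names)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    def frequencies(self) -> np.ndarray:
        """Frequency of the '1' (coded) allele per marker."""
        return self.haplotypes.mean(axis=0)

    def column(self, name: str) -> int:
        return self.names.index(name)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#markers\t" + "\t".join(self.names) + "\n")
            fh.write("#positions\t"
                     + "\t".join(str(int(p)) for p in self.positions) + "\n")
            for row in self.haplotypes:
                fh.write("".join(str(int(a)) for a in row) + "\n")

    @classmethod
    def read(cls, path) -> "HaplotypePanel":
        names, positions, rows = [], [], []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#markers"):
                    names = line.split("\t")[1:]
                elif line.startswith("#positions"):
                    positions = [float(x) for x in line.split("\t")[1:]]
                elif line:
                    rows.append([int(ch) for ch in line])
        return cls(names, np.array(positions), np.array(rows))


def generate_synthetic_panel(n_markers: int = 20, n_haplotypes: int = 200,
                             maf_range=(0.1, 0.5), r2_adjacent: float = 0.2,
                             seed: int = 0, name_prefix: str = "snp",
                             spacing_bp: float = 50_000.0) -> HaplotypePanel:
    """First-order Markov panel with target MAFs and adjacent-marker LD.

    Adjacent markers get correlation rho = sqrt(r2_adjacent); conditional
    allele probabilities follow the standard bivariate-binary construction.
    Raises a configuration error when the (MAF, r2) combination admits no
    valid transition probabilities.
    """
    lo, hi = maf_range
    if not (0 < lo <= hi < 1) or not (0 <= r2_adjacent < 1):
        raise ConfigurationError("invalid maf_range or r2_adjacent")
    rng = np.random.default_rng(seed)
    # sorted along the chromosome: adjacent MAFs stay close, which keeps the
    # target correlation attainable for binary markers
    p = np.sort(rng.uniform(lo, hi, size=n_markers))
    rho = math.sqrt(r2_adjacent)
    H = np.empty((n_haplotypes, n_markers), dtype=np.int8)
    H[:, 0] = rng.random(n_haplotypes) < p[0]
    for m in range(1, n_markers):
        q_prev, q_cur = 1 - p[m - 1], 1 - p[m]
        cov = rho * math.sqrt(p[m - 1] * q_prev * p[m] * q_cur)
        p11 = p[m] + cov / p[m - 1]
        p10 = p[m] - cov / q_prev
        if not (0 <= p11 <= 1 and 0 <= p10 <= 1):
            raise ConfigurationError(
                f"infeasible MAF/r2 combination at marker {m}: "
                f"p={p[m]:.3f} given p_prev={p[m - 1]:.3f}, r2={r2_adjacent}")
        prob = np.where(H[:, m - 1] == 1, p11, p10)
        H[:, m] = rng.random(n_haplotypes) < prob
    names = [f"{name_prefix}{i + 1}" for i in range(n_markers)]
    positions = spacing_bp * (1 + np.arange(n_markers))
    return HaplotypePanel(names, positions, H)


# ---------------------------------------------------------------------------
# gene dropping


DEFAULT_PANEL_PARAMS = dict(n_markers=20, n_haplotypes=200,
                            maf_range=(0.1, 0.5), r2_adjacent=0.2)


@dataclass
class GeneDropResult:
    """Per-pedigree genotypes (allele counts) and founder-descent labels."""

    markers: list[str]
    genotypes: dict          # family_id -> (n, M) int array
    labels: dict             # family_id -> (n, 2, M) int array


def _meiosis_phase(genetic_pos: np.ndarray, rng, recomb: bool) -> np.ndarray:
    """Which parental haplotype (0/1) is transmitted at each marker (Haldane)."""
    start = int(rng.integers(0, 2))
    if not recomb or genetic_pos.size <= 1:
        return np.full(genetic_pos.size, start)
    length = genetic_pos[-1] - genetic_pos[0]
    n_x = rng.poisson(length)
    if n_x == 0:
        return np.full(genetic_pos.size, start)
    xlocs = np.sort(rng.uniform(genetic_pos[0], genetic_pos[-1], size=n_x))
    return (start + np.searchsorted(xlocs, genetic_pos)) % 2


def gene_drop(peds: list[Pedigree], panel: HaplotypePanel,
              cm_per_mb: float = 1.0, recomb: bool = True,
              seed: int = 0, assign: bool = True) -> GeneDropResult:
    """Drop panel haplotypes through pedigrees, tracking descent.

    Founders receive two panel haplotypes sampled uniformly with
    replacement; each meiosis transmits a Haldane-model recombinant of the
    parent's two haplotypes (``recomb=False`` transmits whole haplotypes).
    Descent labels identify the founder haplotype each allele came from.
    With ``assign=True`` the allele counts are stored in each individual's
    genotype map under the panel marker names.
    """
    rng = np.random.default_rng(seed)
    M = panel.n_markers
    gpos = panel.positions / 1e6 * cm_per_mb / 100.0  # Morgans
    genotypes, labels = {}, {}
    label_counter = 0
    for ped in peds:
        n = ped.size
        alle = np.empty((n, 2, M), dtype=np.int8)
        labs = np.empty((n, 2, M), dtype=np.int64)
        parents = ped.parent_indices()
        for i in range(n):
            if parents[i] is None:
                for h in range(2):
                    row = int(rng.integers(0, panel.n_haplotypes))
                    alle[i, h] = panel.haplotypes[row]
                    labs[i, h] = label_counter
                    label_counter += 1
            else:
                for h, par in enumerate(parents[i]):
                    phase = _meiosis_phase(gpos, rng, recomb)
                    alle[i, h] = np.take_along_axis(
                        alle[par], phase[None, :], axis=0)[0]
                    labs[i, h] = np.take_along_axis(
                        labs[par], phase[None, :], axis=0)[0]
        counts = alle.sum(axis=1)
        genotypes[ped.family_id] = counts
        labels[ped.family_id] = labs
        if assign:
            for i, m in enumerate(ped.members):
                for j, name in enumerate(panel.names):
                    m.genotypes[name] = float(counts[i, j])
    return GeneDropResult(list(panel.names), genotypes, labels)


def true_ibd_matrix(ped: Pedigree, labels: np.ndarray,
                    marker_index: int) -> np.ndarray:
    """Realized IBD sharing pi_ij = (alleles shared IBD)/2 at one marker.

    ``labels`` is the (n, 2, M) descent-label array from gene dropping.
    The diagonal is set to 1.
    """
    if marker_index >= labels.shape[2]:
        raise ConfigurationError(f"unknown marker index {marker_index}")
    lab = labels[:, :, marker_index]
    n = lab.shape[0]
    P = np.eye(n)
    for i in range(n):
        a1, a2 = lab[i]
        for j in range(i + 1, n):
            b1, b2 = lab[j]
            # maximum matching between {a1,a2} and {b1,b2}
            if a1 == b1:
                k = 1 + (a2 == b2)
            elif a1 == b2:
                k = 1 + (a2 == b1)
            elif a2 == b1 or a2 == b2:
                k = 1
            else:
                k = 0
            P[i, j] = P[j, i] = k / 2.0
    return P


# ---------------------------------------------------------------------------
# trait simulation


def _psd_factor(Mx: np.ndarray) -> np.ndarray:
    """Square root L (L L' = Mx) of a PSD matrix; error when indefinite."""
    Mx = np.asarray(Mx, dtype=float)
    if Mx.size == 0:
        return Mx.reshape(Mx.shape)
    vals, vecs = np.linalg.eigh(0.5 * (Mx + Mx.T))
    if vals.min() < -1e-8 * max(1.0, vals.max()):
        raise ConfigurationError(
            "a component covariance at the true parameters is not PSD")
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def simulate_phenotypes(peds: list[Pedigree], mm: ModelMatrices,
                        theta_true: np.ndarray, R: dict,
                        seed: int = 0, assign: bool = True) -> dict:
    """Draw trait values under the SEM at ``theta_true``.

    ``R`` maps family_id -> {component: relationship matrix}.  Per pedigree
    and component the latent and observed residuals are matrix-normal with
    row covariance R_c and column covariance Psi_c / Theta_c; traits are
    assembled as y = nu + Lambda eta + Gamma_y x + sum_c eps_c with
    eta = (I - B)^-1 (alpha + Gamma_eta x + sum_c zeta_c).

    Returns {family_id: (n, t) trait matrix}; with ``assign=True`` the
    values are stored in the individuals' phenotype maps.
    """
    rng = np.random.default_rng(seed)
    mats = mm.matrices(np.asarray(theta_true, dtype=float))
    q, t = mm.n_latent, mm.n_observed
    IB_invT = np.linalg.inv(np.eye(q) - mats["B"]).T
    L_psi = {c: _psd_factor(mats[("Psi", c)]) for c in mm.components}
    L_theta = {c: _psd_factor(mats[("Theta", c)]) for c in mm.components}
    rel_factors: dict = {}
    out = {}
    for ped in peds:
        n = ped.size
        x = ped.data_matrix(mm.covariate_vars)  # (n, ncov)
        if np.any(~np.isfinite(x)):
            raise ConfigurationError(
                f"family {ped.family_id}: missing covariate values; run gene "
                "dropping (or supply covariates) before trait simulation")
        Rk = R[ped.family_id]
        facs = {}
        for c in mm.components:
            key = (id(Rk[c]), c)
            if key not in rel_factors:
                rel_factors[key] = _psd_factor(Rk[c])
            facs[c] = rel_factors[key]
        zeta = np.zeros((n, q))
        eps = np.zeros((n, t))
        for c in mm.components:
            if q:
                zeta += facs[c] @ rng.standard_normal((n, q)) @ L_psi[c].T
            eps += facs[c] @ rng.standard_normal((n, t)) @ L_theta[c].T
        v = mats["alpha"][None, :] + x @ mats["Gamma_eta"].T + zeta
        eta = v @ IB_invT
        Y = (mats["nu"][None, :] + eta @ mats["Lambda"].T
             + x @ mats["Gamma_y"].T + eps)
        out[ped.family_id] = Y
        if assign:
            for i, m in enumerate(ped.members):
                for j, name in enumerate(mm.observed_vars):
                    m.phenotypes[name] = float(Y[i, j])
    return out


# ---------------------------------------------------------------------------
# ascertainment


def affection_threshold(mm: ModelMatrices, theta_true: np.ndarray,
                        freqs: dict, prevalence: float,
                        n_ref: int = 100_000, seed: int = 0,
                        traits: list[str] | None = None) -> float:
    """Upper-``prevalence`` quantile of the per-individual mean trait value.

    Computed empirically from a reference population of unrelated
    individuals simulated at the true parameters (genotypes in
    Hardy-Weinberg proportions at the given allele frequencies), because
    the trait-mean distribution is a genotype mixture with no simple
    closed form.
    """
    if not (0 < prevalence < 1):
        raise ConfigurationError("prevalence must be in (0, 1)")
    rng = np.random.default_rng(seed)
    traits = traits or mm.observed_vars
    tsel = [mm.observed_vars.index(v) for v in traits]
    theta_true = np.asarray(theta_true, dtype=float)
    intercept, slopes = implied_mean_coefficients(mm, theta_true)
    V = sum(implied_component_covariance(mm, theta_true, c)
            for c in mm.components)
    A = _psd_factor(V)
    x = np.empty((n_ref, mm.n_covariates))
    for j, cov in enumerate(mm.covariate_vars):
        f = freqs[cov]
        x[:, j] = rng.binomial(2, f, size=n_ref)
    Y = intercept[None, :] + x @ slopes.T \
        + rng.standard_normal((n_ref, mm.n_observed)) @ A.T
    score = Y[:, tsel].mean(axis=1)
    return float(np.quantile(score, 1.0 - prevalence))


def apply_ascertainment(peds: list[Pedigree], prevalence: float,
                        proband_probability: float, threshold: float,
                        seed: int = 0,
                        traits: list[str] | None = None) -> list[Pedigree]:
    """Flag probands and keep only pedigrees that acquired one.

    A member is affected when the mean of its trait values (over
    ``traits``; default all phenotypes present) exceeds ``threshold``.
    Affected members become proband candidates independently with
    probability ``proband_probability``; the first candidate in member
    order is the proband.
    """
    if not (0 < proband_probability <= 1):
        raise ConfigurationError("proband_probability must be in (0, 1]")
    rng = np.random.default_rng(seed)
    kept = []
    for ped in peds:
        proband = None
        for m in ped.members:
            vals = ([m.phenotypes[v] for v in traits] if traits
                    else list(m.phenotypes.values()))
            vals = [v for v in vals if np.isfinite(v)]
            affected = bool(vals) and float(np.mean(vals)) > threshold
            is_candidate = affected and (rng.random() < proband_probability)
            m.proband = False
            if is_candidate and proband is None:
                proband = m
        if proband is not None:
            proband.proband = True
            kept.append(ped)
    return kept


# ---------------------------------------------------------------------------
# pedigree structure presets


def _nuclear(fam: str, n_sibs: int) -> Pedigree:
    members = [Individual("f", sex="male"), Individual("m", sex="female")]
    for s in range(n_sibs):
        members.append(Individual(f"s{s + 1}", "f", "m",
                                  sex="male" if s % 2 == 0 else "female"))
    return Pedigree(fam, members)


def _extended_structures() -> list[Pedigree]:
    def I(pid, f=None, m=None, sex="unknown"):
        return Individual(pid, f, m, sex=sex)

    s1 = Pedigree("E1", [  # three generations with first cousins
        I("g1", sex="male"), I("g2", sex="female"),
        I("c1", "g1", "g2", "male"), I("c2", "g1", "g2", "female"),
        I("sp1", sex="female"), I("sp2", sex="male"),
        I("k1", "c1", "sp1", "male"), I("k2", "c1", "sp1", "female"),
        I("k3", "c1", "sp1", "male"), I("k4", "sp2", "c2", "female")])
    s2 = Pedigree("E2", [  # half-sibs through a shared father
        I("f1", sex="male"), I("w1", sex="female"), I("w2", sex="female"),
        I("k1", "f1", "w1", "male"), I("k2", "f1", "w1", "female"),
        I("k3", "f1", "w2", "male"), I("k4", "f1", "w2", "female"),
        I("sp", sex="female"),
        I("g1", "k1", "sp", "male"), I("g2", "k1", "sp", "female")])
    s3 = Pedigree("E3", [  # classic three-generation family
        I("p1", sex="male"), I("p2", sex="female"),
        I("c1", "p1", "p2", "male"), I("c2", "p1", "p2", "female"),
        I("c3", "p1", "p2", "male"), I("sp1", sex="female"),
        I("g1", "c1", "sp1", "male"), I("g2", "c1", "sp1", "female"),
        I("g3", "c1", "sp1", "male"), I("g4", "c1", "sp1", "female")])
    s4 = Pedigree("E4", [  # loop: first cousins mate
        I("a1", sex="male"), I("a2", sex="female"),
        I("b1", "a1", "a2", "male"), I("b2", "a1", "a2", "female"),
        I("s1", sex="female"), I("s2", sex="male"),
        I("c1", "b1", "s1", "male"), I("c2", "s2", "b2", "female"),
        I("d1", "c1", "c2", "male"), I("d2", "c1", "c2", "female")])
    s5 = Pedigree("E5", [
        I("p1", sex="male"), I("p2", sex="female"),
        I("c1", "p1", "p2", "male"), I("c2", "p1", "p2", "male"),
        I("c3", "p1", "p2", "female"), I("c4", "p1", "p2", "female"),
        I("sp", sex="female"),
        I("g1", "c2", "sp", "male"), I("g2", "c2", "sp", "female"),
        I("g3", "c2", "sp", "male")])
    return [s1, s2, s3, s4, s5]


def preset_pedigrees(name: str) -> list[Pedigree]:
    """Named pedigree structure sets.

    ``nuclear75``: 75 nuclear families, 477 individuals, sibship sizes
    4-11 (69 sibships of four plus one each of 6,7,8,9,10,11).
    ``extended5``: five 10-member three-generation pedigrees including a
    half-sib structure and a consanguineous loop (50 individuals).
    """
    if name == "nuclear75":
        sizes = [4] * 69 + [6, 7, 8, 9, 10, 11]
        peds = [_nuclear(f"N{i + 1:03d}", s) for i, s in enumerate(sizes)]
    elif name == "extended5":
        peds = _extended_structures()
    else:
        raise ConfigurationError(f"unknown pedigree preset {name!r}")
    for i, p in enumerate(peds):
        p.structure_key = i
    return peds


def replicate_structures(templates: list[Pedigree], n: int,
                         start: int = 0) -> list[Pedigree]:
    """Recycle structure templates into ``n`` fresh data-free pedigrees."""
    out = []
    for r in range(n):
        tpl = templates[(start + r) % len(templates)]
        members = [Individual(m.person_id, m.father_id, m.mother_id, m.sex)
                   for m in tpl.members]
        ped = Pedigree(f"{tpl.family_id}r{start + r}", members)
        ped.structure_key = getattr(tpl, "structure_key",
                                    (start + r) % len(templates))
        out.append(ped)
    return out


# ---------------------------------------------------------------------------
# one-call dataset simulation


@dataclass
class SimulationConfig:
    """Everything needed to simulate one dataset."""

    model: object                      # text, ModelSpec, or ModelMatrices
    theta_true: object = 1.0           # scalar, dict name->value, or vector
    structures: object = "nuclear75"   # preset name or list of Pedigree
    n_pedigrees: int = 75
    panel: HaplotypePanel | None = None
    panel_params: dict = field(default_factory=dict)
    ascertainment: dict | None = None  # {prevalence, proband_probability[, traits]}
    seed: int = 0


@dataclass
class SimulatedData:
    peds: list
    ibd: IbdStore | None
    mm: ModelMatrices
    theta_true: np.ndarray
    panel: HaplotypePanel
    threshold: float | None = None
    n_simulated: int = 0


def _compile(model) -> ModelMatrices:
    if isinstance(model, str):
        model = parse_model(model)
    if isinstance(model, ModelSpec):
        model = build_model_matrices(model)
    return model


def _resolve_theta(mm: ModelMatrices, theta_true) -> np.ndarray:
    if isinstance(theta_true, dict):
        return mm.theta_from_dict(theta_true)
    arr = np.asarray(theta_true, dtype=float)
    if arr.ndim == 0:
        return np.full(mm.n_free, float(arr))
    if arr.shape != (mm.n_free,):
        raise ConfigurationError(
            f"theta_true has length {arr.size}, model has {mm.n_free} free "
            "parameters")
    return arr


def _batch_single_marker_drop(parents, m, hap_col, n_haps, rng,
                              label_start=0):
    """Single-locus gene drop for m copies of one pedigree structure.

    Returns (allele counts (m, n), descent labels (m, n, 2), next label).
    """
    n = len(parents)
    alle = np.empty((m, n, 2), dtype=np.int8)
    labs = np.empty((m, n, 2), dtype=np.int64)
    next_label = label_start
    ar = np.arange(m)
    for i in range(n):
        if parents[i] is None:
            rows = rng.integers(0, n_haps, size=(m, 2))
            alle[:, i, :] = hap_col[rows]
            labs[:, i, :] = next_label + np.arange(2 * m).reshape(m, 2)
            next_label += 2 * m
        else:
            for h, par in enumerate(parents[i]):
                pick = rng.integers(0, 2, size=m)
                alle[:, i, h] = alle[ar, par, pick]
                labs[:, i, h] = labs[ar, par, pick]
    return alle.sum(axis=2), labs, next_label


def _batch_ibd_from_labels(labs):
    """(m, n, 2) descent labels -> (m, n, n) realized IBD matrices, diag 1."""
    a1, a2 = labs[:, :, 0], labs[:, :, 1]
    e11 = (a1[:, :, None] == a1[:, None, :]).astype(np.int8)
    e12 = (a1[:, :, None] == a2[:, None, :]).astype(np.int8)
    e21 = (a2[:, :, None] == a1[:, None, :]).astype(np.int8)
    e22 = (a2[:, :, None] == a2[:, None, :]).astype(np.int8)
    k = np.maximum(e11 + e22, e12 + e21)  # max matching of the 2x2 alleles
    P = k / 2.0
    n = labs.shape[1]
    P[:, np.arange(n), np.arange(n)] = 1.0
    return P


def _batch_psd_factor(R):
    """Batched PSD square root via eigendecomposition, (m, n, n)."""
    vals, vecs = np.linalg.eigh(R)
    return vecs * np.sqrt(np.clip(vals, 0.0, None))[..., None, :]


def simulate_dataset(config: SimulationConfig, seed: int | None = None,
                     rel_cache: dict | None = None) -> SimulatedData:
    """Simulate genotypes, traits, (optionally) IBD and ascertainment.

    ``n_pedigrees`` counts *analyzed* pedigrees: under ascertainment,
    batches of structures are simulated until that many pedigrees retain a
    proband.  ``rel_cache`` maps structure_key -> {component: R matrix} and
    is filled on first use, so replicate studies share kinship work.

    Generation is batched per structure template: all copies of one
    structure share relationship-matrix factors, and traits are drawn as
    matrix-normal deviates in one vectorized pass.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    mm = _compile(config.model)
    theta = _resolve_theta(mm, config.theta_true)

    panel = config.panel
    if panel is None:
        pp = dict(DEFAULT_PANEL_PARAMS, seed=int(rng.integers(0, 2**31 - 1)))
        pp.update(config.panel_params)
        panel = generate_synthetic_panel(**pp)

    # markers the model needs: covariates + linkage components
    linkage_comps = [c for c in mm.components if component_marker(c)]
    needed = list(dict.fromkeys(
        list(mm.covariate_vars)
        + [component_marker(c) for c in linkage_comps]))
    # markers named in the model but absent from the panel are assigned
    # panel columns starting from the middle: with frequencies sorted along
    # the chromosome this stands in for a randomly chosen *common* marker
    marker_col = {}
    fallback = 0
    for name in needed:
        if name in panel.names:
            marker_col[name] = panel.column(name)
        else:
            marker_col[name] = (panel.n_markers // 2
                                + fallback) % panel.n_markers
            fallback += 1

    templates = (preset_pedigrees(config.structures)
                 if isinstance(config.structures, str) else
                 list(config.structures))
    asc = config.ascertainment
    threshold = None
    if asc:
        traits = asc.get("traits")
        thr_seed = int(rng.integers(0, 2**31 - 1))
        threshold = asc.get("threshold")
        if threshold is None:
            threshold = affection_threshold(
                mm, theta, {c: panel.frequencies()[marker_col[c]]
                            for c in mm.covariate_vars},
                asc["prevalence"],
                n_ref=asc.get("n_ref", 100_000),
                seed=thr_seed, traits=traits)

    if rel_cache is None:
        rel_cache = {}

    def structure_rels(ped):
        key = getattr(ped, "structure_key", None)
        if key is not None and key in rel_cache:
            return dict(rel_cache[key])
        rel = {}
        for c in mm.components:
            if c == "e":
                rel[c] = np.eye(ped.size)
            elif c == "p":
                rel[c] = 2.0 * kinship_matrix(ped)
            elif c == "c":
                rel[c] = np.ones((ped.size, ped.size))
        if key is not None:
            rel_cache[key] = dict(rel)
        return rel

    # fixed quantities for batched trait simulation
    mats = mm.matrices(theta)
    q_lat, t_obs = mm.n_latent, mm.n_observed
    IB_invT = np.linalg.inv(np.eye(q_lat) - mats["B"]).T
    L_psi = {c: _psd_factor(mats[("Psi", c)]) for c in mm.components}
    L_theta = {c: _psd_factor(mats[("Theta", c)]) for c in mm.components}
    asc_traits = (asc.get("traits") if asc else None) or mm.observed_vars
    asc_idx = [mm.observed_vars.index(v) for v in asc_traits]
    struct_factors: dict = {}

    def structure_factor(tpl, g, c):
        key = (getattr(tpl, "structure_key", g), c)
        if key not in struct_factors:
            struct_factors[key] = _psd_factor(structure_rels(tpl)[c])
        return struct_factors[key]

    def generate_batch(tpl, g, m):
        """m copies of one structure: genotypes, descent labels, traits."""
        n = tpl.size
        parents = tpl.parent_indices()
        counts, labs = {}, {}
        for name, col in marker_col.items():
            counts[name], labs[name], _ = _batch_single_marker_drop(
                parents, m, panel.haplotypes[:, col], panel.n_haplotypes, rng)
        if mm.covariate_vars:
            x = np.stack([counts[c] for c in mm.covariate_vars],
                         axis=2).astype(float)
        else:
            x = np.zeros((m, n, 0))
        facs = {}
        for c in mm.components:
            mk = component_marker(c)
            if mk is None:
                facs[c] = structure_factor(tpl, g, c)
            else:
                facs[c] = _batch_psd_factor(_batch_ibd_from_labels(labs[mk]))
        zeta = np.zeros((m, n, q_lat))
        eps = np.zeros((m, n, t_obs))
        for c in mm.components:
            F = facs[c]
            if q_lat:
                zeta += F @ rng.standard_normal((m, n, q_lat)) @ L_psi[c].T
            eps += F @ rng.standard_normal((m, n, t_obs)) @ L_theta[c].T
        v = mats["alpha"][None, None, :] + x @ mats["Gamma_eta"].T + zeta
        eta = v @ IB_invT
        Y = (mats["nu"][None, None, :] + eta @ mats["Lambda"].T
             + x @ mats["Gamma_y"].T + eps)
        return counts, labs, Y

    retained: list[Pedigree] = []
    kept_labels: dict = {name: [] for name in needed}
    fam_counter = 0
    n_simulated = 0
    T = len(templates)
    while len(retained) < config.n_pedigrees:
        need = config.n_pedigrees - len(retained)
        if not asc:
            chunk = need
        elif n_simulated == 0:
            # expected per-member candidate probability gives a first guess
            mean_size = float(np.mean([tp.size for tp in templates]))
            p_keep = 1.0 - (1.0 - asc["prevalence"]
                            * asc["proband_probability"]) ** mean_size
            chunk = int(1.3 * need / max(p_keep, 1e-4)) + 50
        else:
            rate = max(len(retained) / n_simulated, 1.0 / n_simulated)
            chunk = int(1.3 * need / rate) + 50
        n_simulated += chunk
        per_tpl = [chunk // T + (1 if g < chunk % T else 0) for g in range(T)]
        for g, tpl in enumerate(templates):
            m = per_tpl[g]
            if m == 0:
                continue
            counts, labs, Y = generate_batch(tpl, g, m)
            n = tpl.size
            if asc:
                score = Y[:, :, asc_idx].mean(axis=2)
                cand = (score > threshold) & (
                    rng.random((m, n)) < asc["proband_probability"])
                keep_rows = np.nonzero(cand.any(axis=1))[0]
                first = cand.argmax(axis=1)
            else:
                keep_rows = np.arange(m)
                first = np.full(m, -1)
            for row in keep_rows:
                if len(retained) >= config.n_pedigrees:
                    break
                members = []
                for i, mem in enumerate(tpl.members):
                    ind = Individual(mem.person_id, mem.father_id,
                                     mem.mother_id, mem.sex)
                    ind.phenotypes = {v: float(Y[row, i, j])
                                      for j, v in enumerate(mm.observed_vars)}
                    ind.genotypes = {name: float(counts[name][row, i])
                                     for name in marker_col}
                    ind.proband = bool(asc) and i == first[row]
                    members.append(ind)
                ped = Pedigree(f"{tpl.family_id}r{fam_counter}", members)
                fam_counter += 1
                ped.structure_key = getattr(tpl, "structure_key", g)
                retained.append(ped)
                for name in needed:
                    kept_labels[name].append(labs[name][row])
        if not asc:
            break
        if n_simulated > 2_000_000:
            raise ConfigurationError(
                "ascertainment retained too few pedigrees; increase "
                "prevalence or proband probability")
    if len(retained) < config.n_pedigrees:
        raise ConfigurationError(
            f"only {len(retained)} pedigrees available; requested "
            f"{config.n_pedigrees}")

    ibd = None
    if linkage_comps:
        ibd = IbdStore()
        for c in linkage_comps:
            mk = component_marker(c)
            for pidx, ped in enumerate(retained):
                lab = kept_labels[mk][pidx]
                P = true_ibd_matrix(ped, lab[:, :, None], 0)
                ids = [mmb.person_id for mmb in ped.members]
                for i in range(ped.size):
                    for j in range(i + 1, ped.size):
                        ibd.set(ped.family_id, mk, ids[i], ids[j], P[i, j])
    return SimulatedData(peds=retained, ibd=ibd, mm=mm, theta_true=theta,
                         panel=panel, threshold=threshold,
                         n_simulated=n_simulated)
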