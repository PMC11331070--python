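"""Synthetic metapopulation data generator.

Emulates the study conditions of a highly dynamic butterfly metapopulation:
a few hundred host-plant patches of which roughly 20% are occupied in a
given fall, local populations of 1 to ~94 larval nests (median 3) with a
median continuous occupancy of about two years, three larvae genotyped per
nest at a panel of biallelic SNPs, and population expected heterozygosity
moderately correlated (r ~ 0.6) with log population size.

Yearly cycle for each patch (fall of year t to fall of year t+1):

1.  Fall census: occupied patches hold N_t nests; each nest carries an
    inbreeding coefficient F around the population-level F (which
    accumulates by the drift recursion f <- f + (1-f)/(2*N_t) per year and
    resets on recolonization).
2.  Overwinter: every nest survives independently with probability
    S0*exp(-b_true*F); in addition a patch-level winter catastrophe strikes
    with logistic probability (log odds: ext_intercept + ext_slope_h*H +
    demographic terms on centred log N, log area and log connectivity),
    killing all nests.  Spring count = surviving nests; a spring count of
    zero is an overwinter extinction.
3.  Summer: patches with spring survivors grow to next fall's count
    (stochastic growth, capped by an area-based carrying capacity, at least
    one nest — all true extinction happens overwinter).  Patches extinct
    overwinter may be rescued (recolonized before the next fall census)
    with probability increasing in connectivity times ``rescue_scale``;
    unoccupied patches are colonized with probability 1 - exp(-c*S_i),
    with c calibrated during burn-in so occupancy settles at
    ``target_occupancy``.
4.  Allele frequencies per patch drift binomially with effective size
    proportional to nest count, receive migrant alleles in proportion to
    connectivity, and are re-founded from four haploid genome copies (one
    mated female) on colonization.

Genotypes: each nest is one full-sib family; two parents are drawn from
the patch allele frequencies with heterozygote deficit 2pq(1-F), and the
genotyped larvae are Mendelian offspring of that pair.  A small fraction of
nests receive a second family (merged nests); calls are set missing
independently at ``missing_call_rate``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .hetcalc import GenotypeTable

__all__ = [
    "GeneratorConfig",
    "SimulatedDataset",
    "generate_patches",
    "simulate_dynamics",
    "simulate",
    "write_dataset",
    "read_dataset",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic metapopulation.

    Defaults are desk-scale but statistically calibrated to the field
    system: ~20% fall occupancy, occupied-patch nest counts with median 3
    and maximum below ~94, nest survival S0*exp(-B*F) with S0 = 0.7, and
    population He correlated ~0.6 with log nest count.
    """

    n_patches: int = 400
    extent_km: tuple[float, float] = (20.0, 20.0)
    n_years: int = 10
    n_loci: int = 245
    founder_maf_range: tuple[float, float] = (0.2, 0.5)
    target_occupancy: float = 0.20
    s0: float = 0.7
    b_true: float = 2.5
    ext_intercept: float = 1.58
    ext_slope_h: float = -6.14
    demo_slopes: tuple[float, float, float] = (-0.8, -0.2, -0.3)
    rescue_scale: float = 1.0
    larvae_genotyped_per_nest: int = 3
    merged_nest_fraction: float = 0.05
    missing_call_rate: float = 0.02
    seed: int = 0
    # dynamics internals (not part of the headline study conditions)
    alpha: float = 1.0  # dispersal kernel rate, 1/km
    burn_in: int = 60
    growth_rate: float = 5.0  # fall nests per surviving spring nest
    growth_noise_sigma: float = 1.0  # patch-year lognormal environmental noise on growth
    year_noise_sigma: float = 0.4  # shared good/bad-year lognormal noise on growth
    area_capacity: float = 4.0  # nest carrying capacity per unit area
    cap_max: int = 94  # largest local population the habitat supports
    founding_mean: float = 2.0  # mean extra nests founded at (re)colonization
    drift_copies_per_nest: int = 8  # genome copies per nest for drift strength
    f_noise_sd: float = 0.10  # nest-to-nest spread of F around the population F
    migration_scale: float = 0.5  # migrant genome copies per unit connectivity
    colonist_copies: int = 4  # haploid genomes per founding female
    founding_females_mean: float = 1.0  # extra founding females ~ Poisson(mean)
    ne_noise_sigma: float = 1.2  # lognormal spread of per-patch-year effective size
    pool_anchor: float = 0.5  # weight of the wider-metapopulation gene pool in migrants

    def __post_init__(self):
        for name in ("target_occupancy", "s0", "merged_nest_fraction", "missing_call_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.n_patches < 2:
            raise ValueError("need at least 2 patches")
        lo, hi = self.founder_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("founder_maf_range must lie within (0, 0.5]")
        if self.extent_km[0] <= 0 or self.extent_km[1] <= 0:
            raise ValueError("extent must be positive")
        if self.n_years < 3:
            raise ValueError("n_years must be >= 3 (trend classification needs t-2)")
        if self.larvae_genotyped_per_nest < 1:
            raise ValueError("must genotype at least one larva per nest")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["extent_km"] = list(self.extent_km)
        d["founder_maf_range"] = list(self.founder_maf_range)
        d["demo_slopes"] = list(self.demo_slopes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for k in ("extent_km", "founder_maf_range", "demo_slopes"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class SimulatedDataset:
    patches: pd.DataFrame
    survey: pd.DataFrame
    nests: pd.DataFrame
    genotypes: GenotypeTable
    config: GeneratorConfig


def generate_patches(config: GeneratorConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Patch coordinates, areas and habitat-quality scores.

    Placement is uniform within the extent; areas are lognormal
    (right-skewed); host-plant abundance is ordinal 1-3 and the dry /
    low-vegetation / grazed proportions are Beta-distributed fractions.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = config.n_patches
    w, h = config.extent_km
    return pd.DataFrame(
        {
            "patch_id": [f"P{i:04d}" for i in range(n)],
            "x_km": rng.uniform(0, w, n),
            "y_km": rng.uniform(0, h, n),
            "area": np.exp(rng.normal(0.0, 1.0, n)),
            "host_abundance": rng.choice([1, 2, 3], n, p=[0.5, 0.35, 0.15]),
            "prop_dry": rng.beta(1.5, 6.0, n),
            "prop_low_veg": rng.beta(3.0, 3.0, n),
            "prop_grazed": rng.beta(1.2, 5.0, n),
            "region": "synthetic",
        }
    )


def _kernel(patches: pd.DataFrame, alpha: float) -> np.ndarray:
    xy = patches[["x_km", "y_km"]].to_numpy(dtype=float)
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2))
    k = np.exp(-alpha * d)
    np.fill_diagonal(k, 0.0)
    return k


class _State:
    """Mutable per-patch state carried across simulated years."""

    def __init__(self, config: GeneratorConfig, patches: pd.DataFrame, rng: np.random.Generator):
        n, L = config.n_patches, config.n_loci
        self.p_meta = rng.uniform(*config.founder_maf_range, L)  # metapopulation frequencies
        self.freq = np.tile(self.p_meta, (n, 1))
        self.N = np.zeros(n, dtype=int)
        self.f_pop = np.zeros(n)
        init = rng.random(n) < config.target_occupancy
        self.N[init] = 1 + rng.poisson(2.0, init.sum())
        self.area = patches["area"].to_numpy(dtype=float)
        self.cap = np.clip(
            np.round(config.area_capacity * self.area), 1, config.cap_max
        ).astype(int)


def _true_het(freq: np.ndarray) -> np.ndarray:
    """Mean 2pq over loci per patch."""
    return (2.0 * freq * (1.0 - freq)).mean(axis=1)


def _migrant_pool(state: _State, anchor: float) -> np.ndarray:
    """Allele frequencies of dispersers.

    A mixture of the occupied patches (abundance-weighted) and the founder
    metapopulation frequencies; the anchor represents immigration from the
    wider patch network outside the simulated study region and keeps the
    metapopulation-wide gene diversity stationary.
    """
    occ = state.N > 0
    if not occ.any():
        return state.p_meta
    w = state.N[occ].astype(float)
    local = (state.freq[occ] * w[:, None]).sum(axis=0) / w.sum()
    return (1.0 - anchor) * local + anchor * state.p_meta


def _winter(state, config, s_prev, nest_f, rng):
    """Patch-level winter catastrophe draw.

    The target patch extinction probability is logistic in heterozygosity
    plus centred demographic covariates (log nest count, log area, log
    connectivity).  Nest-level deaths already make a patch go extinct when
    every nest dies; the catastrophe supplies the *residual* hazard so the
    total overwinter extinction probability equals the logistic model
    wherever the emergent risk does not already exceed it.
    """
    n = config.n_patches
    occ = state.N > 0
    het = _true_het(state.freq)
    logn = np.where(occ, np.log(np.maximum(state.N, 1)), 0.0)
    log_area = np.log(state.area)
    with np.errstate(divide="ignore"):
        log_s = np.where(s_prev > 0, np.log(np.maximum(s_prev, 1e-12)), 0.0)
    d1, d2, d3 = config.demo_slopes
    # demographic terms centred on typical values so the H term sets the level
    eta = (
        config.ext_intercept
        + config.ext_slope_h * het
        + d1 * (logn - np.log(3.0))
        + d2 * (log_area - log_area.mean())
        + d3 * (log_s - (log_s[occ].mean() if occ.any() else 0.0))
    )
    p_target = 1.0 / (1.0 + np.exp(-eta))
    # emergent extinction risk: probability every nest dies of its own accord
    p_all_die = np.ones(n)
    for i in np.where(occ)[0]:
        surv = config.s0 * np.exp(-config.b_true * nest_f[i])
        p_all_die[i] = np.prod(1.0 - surv)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_resid = np.clip((p_target - p_all_die) / (1.0 - p_all_die), 0.0, 1.0)
    p_resid = np.where(p_all_die >= 1.0, 0.0, p_resid)
    catastrophe = occ & (rng.random(n) < p_resid)
    return catastrophe


def _solve_colonization_rate(s_empty: np.ndarray, deficit: float, c_prev: float) -> float:
    """Rate constant c with sum(1 - exp(-c*S_empty)) = deficit (expected
    colonizations filling the occupancy deficit); monotone bisection."""
    c_min = 1e-4
    usable = s_empty[s_empty > 0]
    if deficit <= 0 or usable.size == 0:
        return c_min
    if deficit >= usable.size:  # cannot exceed one colonization per patch
        return 10.0
    lo, hi = 1e-6, 10.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if np.sum(1.0 - np.exp(-mid * usable)) < deficit:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_dynamics(
    patches: pd.DataFrame, config: GeneratorConfig
) -> tuple[pd.DataFrame, pd.DataFrame, GenotypeTable]:
    """Run burn-in plus ``n_years`` recorded years; return survey, nests, genotypes."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = config.n_patches
    kernel = _kernel(patches, config.alpha)
    state = _State(config, patches, rng)
    c_col = 0.05  # colonization rate constant, re-calibrated every year
    s_prev = kernel @ state.N.astype(float)

    survey_rows: list[tuple] = []
    nest_rows: list[tuple] = []
    geno_chunks: list[tuple] = []
    patch_ids = patches["patch_id"].to_numpy()

    total_years = config.burn_in + config.n_years
    for step in range(total_years):
        recording = step >= config.burn_in
        year = step - config.burn_in + 1  # recorded years are 1..n_years
        occ = state.N > 0

        # --- fall census and nest-level state ---
        nest_f = {}
        for i in np.where(occ)[0]:
            f = np.clip(
                state.f_pop[i] + rng.normal(0.0, config.f_noise_sd, state.N[i]), 0.0, 1.0
            )
            nest_f[i] = f
        if recording:
            for i in range(n):
                survey_rows.append((patch_ids[i], year, "fall", int(state.N[i])))

        # --- overwinter survival ---
        catastrophe = _winter(state, config, s_prev, nest_f, rng)
        spring = np.zeros(n, dtype=int)
        survived = {}
        for i in np.where(occ)[0]:
            if catastrophe[i]:
                alive = np.zeros(state.N[i], dtype=bool)
            else:
                p_surv = config.s0 * np.exp(-config.b_true * nest_f[i])
                alive = rng.random(state.N[i]) < p_surv
            survived[i] = alive
            spring[i] = int(alive.sum())
        if recording:
            for i in range(n):
                survey_rows.append((patch_ids[i], year, "spring", int(spring[i])))
            for i in np.where(occ)[0]:
                for j in range(state.N[i]):
                    nest_rows.append(
                        (
                            f"N{year:02d}_{patch_ids[i]}_{j:03d}",
                            patch_ids[i],
                            year,
                            nest_f[i][j],
                            int(survived[i][j]),
                            int(catastrophe[i]),
                        )
                    )
            geno_chunks.append((year, {i: (state.N[i], nest_f[i]) for i in np.where(occ)[0]},
                                state.freq.copy()))

        # --- summer: growth, rescue, colonization ---
        s_now = kernel @ state.N.astype(float)  # connectivity from this fall's counts
        new_N = np.zeros(n, dtype=int)
        grew = spring > 0
        # growth is environmentally noisy: a metapopulation-wide year effect
        # plus independent patch-year variation (weather, habitat condition)
        year_mult = np.exp(
            rng.normal(0.0, config.year_noise_sigma) - config.year_noise_sigma**2 / 2
        )
        patch_mult = np.exp(
            rng.normal(0.0, config.growth_noise_sigma, grew.sum())
            - config.growth_noise_sigma**2 / 2
        )
        new_N[grew] = np.minimum(
            state.cap[grew],
            np.maximum(
                1,
                rng.poisson(config.growth_rate * year_mult * patch_mult * spring[grew]),
            ),
        )
        winter_extinct = occ & (spring == 0)
        if config.rescue_scale > 0:
            p_resc = 1.0 - np.exp(-config.rescue_scale * c_col * s_now)
            rescued = winter_extinct & (rng.random(n) < p_resc)
        else:
            rescued = np.zeros(n, dtype=bool)
        # colonization of patches that were already empty last fall; the rate
        # constant is re-calibrated each year so that expected occupancy sits
        # at the target (regional colonization pressure balances extinction)
        empty = ~occ
        deficit = config.target_occupancy * n - float((grew | rescued).sum())
        s_empty = s_now[empty]
        c_col = _solve_colonization_rate(s_empty, deficit, c_col)
        p_colon = 1.0 - np.exp(-c_col * s_now)
        colonized = empty & (rng.random(n) < p_colon)
        founders = rescued | colonized
        new_N[founders] = 1 + rng.poisson(config.founding_mean, founders.sum())

        # --- genetic state update ---
        pool = _migrant_pool(state, config.pool_anchor)
        persist = grew
        if persist.any():
            # the overwinter survivors are the breeders: drift and
            # inbreeding accumulate through that bottleneck, so a declining
            # population (few spring nests) loses diversity and gains F
            # fast; reproductive skew and shared environment additionally
            # spread the realized effective size around its expectation
            ne_mult = np.exp(
                rng.normal(0.0, config.ne_noise_sigma, persist.sum())
                - config.ne_noise_sigma**2 / 2
            )
            breeders = spring[persist]
            copies = np.maximum(
                4, (config.drift_copies_per_nest * breeders * ne_mult).astype(int)
            )
            m = config.migration_scale * s_now[persist]
            mrate = m / (m + copies)
            pf = (1 - mrate[:, None]) * state.freq[persist] + mrate[:, None] * pool
            state.freq[persist] = rng.binomial(copies[:, None], pf) / copies[:, None]
            # drift accumulates inbreeding; immigrant ancestry dilutes it
            fp = state.f_pop[persist]
            fp = fp + (1.0 - fp) / (2.0 * breeders)
            state.f_pop[persist] = fp * (1.0 - mrate)
        if founders.any():
            # each founding female comes from one source patch, sampled by
            # distance-weighted abundance; one or a few females (4 genome
            # copies each) found the new gene pool
            occ_idx = np.where(occ)[0]
            w_src = kernel[:, occ_idx] * state.N[occ_idx] if len(occ_idx) else None
            for i in np.where(founders)[0]:
                k = config.colonist_copies * (
                    1 + rng.poisson(config.founding_females_mean)
                )
                src_p = pool
                if w_src is not None:
                    wi = w_src[i]
                    tot = wi.sum()
                    if tot > 0:
                        src = occ_idx[rng.choice(len(occ_idx), p=wi / tot)]
                        src_p = (1 - config.pool_anchor) * state.freq[src] + (
                            config.pool_anchor * state.p_meta
                        )
                founded = rng.binomial(k, src_p) / k
                # other immigrants arriving in the same dispersal season
                # dilute the founder bottleneck in proportion to connectivity
                m_i = config.migration_scale * s_now[i]
                mrate_i = m_i / (m_i + k)
                state.freq[i] = (1 - mrate_i) * founded + mrate_i * pool
            state.f_pop[founders] = 0.0
        died = occ & (spring == 0) & ~rescued
        state.f_pop[died] = 0.0
        state.N = new_N
        s_prev = s_now

    survey = pd.DataFrame(survey_rows, columns=["patch_id", "year", "season", "nest_count"])
    nests, genotypes = _emit_genotypes(config, patch_ids, geno_chunks, nest_rows, rng)
    return survey, nests, genotypes


def _emit_genotypes(config, patch_ids, geno_chunks, nest_rows, rng):
    """Draw full-sib genotypes for every recorded nest (vectorized per year)."""
    L = config.n_loci
    k_larvae = config.larvae_genotyped_per_nest
    nests = pd.DataFrame(
        nest_rows,
        columns=[
            "nest_id",
            "patch_id",
            "year",
            "f_true",
            "survived_overwinter",
            "patch_catastrophe",
        ],
    )
    nests["n_families"] = 1

    metas = []
    call_blocks = []
    merged_flags = {}
    for year, per_patch, freq in geno_chunks:
        nest_list = []  # (nest_id, patch_idx, f)
        for i, (cnt, fvals) in per_patch.items():
            for j in range(cnt):
                nest_list.append((f"N{year:02d}_{patch_ids[i]}_{j:03d}", i, fvals[j]))
        if not nest_list:
            continue
        m = len(nest_list)
        pidx = np.array([t[1] for t in nest_list])
        fvec = np.array([t[2] for t in nest_list])
        p = freq[pidx]  # (m, L) patch allele frequencies per nest

        def parent_pair(f, p, size_m):
            """Allele pairs of two parents with kinship (and inbreeding) F.

            Parent A is drawn with heterozygote deficit 2pq(1-F); parent B's
            alleles are identical-by-descent copies of A's with probability
            2F each (giving the pair kinship F, hence offspring inbreeding
            F), otherwise fresh draws from the patch frequencies.  At F = 0
            both parents are independent Hardy-Weinberg draws.
            """
            q = 1.0 - p
            f_ = f[:, None]
            probs_het = 2 * p * q * (1 - f_)
            probs_alt2 = p**2 + f_ * p * q
            u = rng.random((size_m, L))
            ga = np.where(u < probs_alt2, 2, np.where(u < probs_alt2 + probs_het, 1, 0))
            coin = rng.random((size_m, L)) < 0.5
            a1 = np.where(ga == 2, 1, np.where((ga == 1) & coin, 1, 0))
            a2 = ga - a1
            pb = []
            for _ in range(2):
                pick = np.where(rng.random((size_m, L)) < 0.5, a1, a2)
                fresh = (rng.random((size_m, L)) < p).astype(a1.dtype)
                copy = rng.random((size_m, L)) < np.minimum(1.0, 2.0 * f_)
                pb.append(np.where(copy, pick, fresh))
            b1, b2 = pb
            return (a1, a2), (b1, b2)

        merged = rng.random(m) < config.merged_nest_fraction
        fam1_a, fam1_b = parent_pair(fvec, p, m)
        # second family for merged nests, same patch frequencies
        fam2_a, fam2_b = parent_pair(fvec, p, m)

        # larvae of nest t occupy rows t*k .. t*k+k-1
        year_calls = np.empty((m * k_larvae, L), dtype=np.int8)
        meta = {"individual_id": [], "nest_id": [], "patch_id": [], "year": []}
        for child in range(k_larvae):
            # last larva of a merged nest comes from the second family
            use2 = merged & (child == k_larvae - 1) if k_larvae > 1 else merged
            u2 = use2[:, None]

            def mendel(par):
                a1, a2 = par
                pick = rng.random((m, L)) < 0.5
                return np.where(pick, a1, a2)

            al1 = np.where(u2, mendel(fam2_a), mendel(fam1_a))
            al2 = np.where(u2, mendel(fam2_b), mendel(fam1_b))
            year_calls[child::k_larvae] = (al1 + al2).astype(np.int8)
        miss = rng.random((m * k_larvae, L)) < config.missing_call_rate
        year_calls[miss] = -1
        for t, (nest_id, i, _) in enumerate(nest_list):
            for child in range(k_larvae):
                meta["individual_id"].append(f"{nest_id}_L{child}")
                meta["nest_id"].append(nest_id)
                meta["patch_id"].append(patch_ids[i])
                meta["year"].append(year)
            merged_flags[nest_id] = 2 if merged[t] else 1
        metas.append(pd.DataFrame(meta))
        call_blocks.append(year_calls)

    if metas:
        meta_all = pd.concat(metas, ignore_index=True)
        calls = np.vstack(call_blocks)
    else:
        meta_all = pd.DataFrame(
            {"individual_id": [], "nest_id": [], "patch_id": [], "year": []}
        )
        calls = np.zeros((0, L), dtype=np.int8)
    locus_names = [f"locus_{j + 1:04d}" for j in range(L)]
    nests["n_families"] = nests["nest_id"].map(merged_flags).fillna(1).astype(int)
    gt = GenotypeTable(meta=meta_all, calls=calls, locus_names=locus_names)
    return nests, gt


def simulate(config: GeneratorConfig) -> SimulatedDataset:
    """Generate a full synthetic dataset (patches, surveys, nests, genotypes)."""
    patches = generate_patches(config)
    survey, nests, genotypes = simulate_dynamics(patches, config)
    return SimulatedDataset(patches, survey, nests, genotypes, config)


def write_dataset(ds: SimulatedDataset, out_dir) -> dict[str, Path]:
    """Write CSV files plus a provenance record of the config and seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "patches": out / "patches.csv",
        "survey": out / "survey.csv",
        "nests": out / "nests.csv",
        "genotypes": out / "genotypes.csv",
        "provenance": out / "provenance.yaml",
    }
    ds.patches.to_csv(paths["patches"], index=False)
    ds.survey.to_csv(paths["survey"], index=False)
    ds.nests.to_csv(paths["nests"], index=False)
    ds.genotypes.to_frame().to_csv(paths["genotypes"], index=False)
    with open(paths["provenance"], "w") as fh:
        yaml.safe_dump({"config": ds.config.to_dict(), "seed": ds.config.seed}, fh)
    return paths


def read_dataset(in_dir) -> SimulatedDataset:
    """Read back a dataset written by :func:`write_dataset`."""
    from .covars import read_nests, read_patches, read_survey
    from .hetcalc import read_genotypes

    d = Path(in_dir)
    with open(d / "provenance.yaml") as fh:
        prov = yaml.safe_load(fh)
    return SimulatedDataset(
        patches=read_patches(d / "patches.csv"),
        survey=read_survey(d / "survey.csv"),
        nests=read_nests(d / "nests.csv"),
        genotypes=read_genotypes(d / "genotypes.csv"),
        config=GeneratorConfig.from_dict(prov["config"]),
    )
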