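"""Synthetic-data generators matching the statistical structure of the study.

Every downstream stage of the pipeline can be exercised at desk scale with
known ground truth:

* ``gen_landmarks`` — head-shape landmark configurations: per-group mean
  shapes plus shared pitch/yaw projection-artifact deformation fields (a 3D
  head photographed in 2D), one anisotropic biological within-group axis,
  isotropic digitizing noise, and a random similarity transform per
  specimen.  True nuisance scores are recorded for recovery tests.
* ``gen_backcross`` — marker genotypes and organ phenotypes for a backcross
  of F1 hybrid females to recurrent-parent males: independent chromosome
  segregation, additive per-chromosome eye effects, a latent body-size
  confounder acting on all organs, plus optional linked-marker
  recombinants and contaminant individuals.
* ``gen_poolseq`` — an F18 advanced intercross maintained by brother-sister
  mating: one F1 pair founds a set of full-sib chains; meioses recombine by
  a Poisson crossover process with crossovers suppressed inside inversion
  intervals for inversion heterokaryotypes; phenotyped F18 females are
  partitioned into quartile pools and read counts are drawn binomially at
  approximately normal coverage.
* ``gen_population_pools`` — two population pools with allele-frequency
  differentiation planted only inside inversion intervals.
* ``gen_tree_traits`` — Brownian-motion trait evolution on a small rooted
  phylogeny from a known root state.

All generators are bit-reproducible given (seed, config); each derives its
own stream from the config seed and a generator-specific tag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from . import backcross as bc
from . import poolgwas
from .morpho import LandmarkConfiguration
from .phylo import TraitTree

__all__ = [
    "SimConfig",
    "LandmarkSample",
    "BackcrossSample",
    "PoolseqSample",
    "PopulationPoolSample",
    "gen_landmarks",
    "gen_backcross",
    "gen_poolseq",
    "gen_population_pools",
    "gen_tree_traits",
]

_DEFAULT_TREE = (
    "((virilis:2.0,(novamexicana:0.9,(americana_north:0.45,"
    "americana_south:0.45):0.45):1.1):0.5,virilis_out:2.5);"
)


@dataclass
class SimConfig:
    """Study-condition parameters for all generators.

    Defaults emulate the published experimental design: 43 landmarks,
    backcross effects of +4.1/+3.5/+2.3% on relative eye size for the 4th,
    fused 2nd-3rd and 5th chromosomes with residual noise calibrated to
    R-squared of 0.153/0.110/0.048 at n = 552; 157 F18 females pooled into
    quartiles sequenced at ~80x coverage; 17 generations of sib mating.
    """

    seed: int = 0

    # --- landmarks ---------------------------------------------------------
    n_landmarks: int = 43
    groups: tuple = (("novamexicana", 30, 0.05), ("americana_sf", 30, 0.05))
    nuisance_amplitudes: tuple = (0.05, 0.01)    # (pitch, yaw) score s.d.
    bio_amplitude: float = 0.022                 # anisotropic biological axis
    landmark_noise_sd: float = 0.002             # isotropic, per coordinate

    # --- backcross ---------------------------------------------------------
    n_individuals_backcross: int = 559
    backcross_effects: dict = field(
        default_factory=lambda: {"X": 0.0, "c4": 0.041, "c23": 0.035, "c5": 0.023})
    backcross_body_effects: dict = field(default_factory=lambda: {"c5": 0.03})
    backcross_noise_frac: float = 0.0436   # residual sd as fraction of hom mean
    backcross_baseline_eye: float = 250000.0   # µm², hom-class relative eye size
    recombinant_prob: float = 4 / 559      # discordance within one linked pair
    contaminant_prob: float = 3 / 559      # impossible donor-homozygote calls
    body_size_sd: float = 0.05             # latent linear-scale s.d.

    # --- pool-seq ----------------------------------------------------------
    n_chromosomes: int = 4
    chrom_length: float = 25e6
    n_snps: int = 20000
    inversion_intervals: tuple = (("chr1", 8_000_000, 10_000_000),)
    n_causal_snps: int = 1
    causal_effect: float = 1.0
    causal_inside_inversion: bool = True
    poolseq_noise_sd: float = 0.5
    crossovers_per_chrom: float = 1.0
    n_lines: int = 50          # full-sib chains founded by the F1 pair
    n_generations: int = 17    # meiotic generations F1 -> F18
    coverage_mean: float = 80.0
    coverage_sd: float = 15.0
    n_individuals_pool: int = 157
    # read-sampling null: every pool's reads are drawn at the common
    # population allele frequency (same DNA pooled four ways), which is the
    # exact null of the Fisher read-count test.  The default (False) pools
    # the actual quartile members, whose true frequencies differ by
    # individual sampling - a realistic overdispersion that makes the
    # read-count test anti-conservative on null data.
    null_common_pools: bool = False

    # --- population pools --------------------------------------------------
    pop_freq_inside: tuple = (0.9, 0.1)    # (south, north) inside intervals
    pop_freq_outside: float = 0.5
    n_individuals_per_population: int = 50

    # --- tree traits -------------------------------------------------------
    bm_sigma2: float = 1.0
    bm_root_state: float = 0.0
    tree_newick: str = _DEFAULT_TREE

    def __post_init__(self) -> None:
        for name in ("n_landmarks", "n_chromosomes", "n_snps", "n_lines",
                     "n_generations", "n_individuals_pool",
                     "n_individuals_backcross", "n_individuals_per_population"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for chrom, start, end in self.inversion_intervals:
            if not (0 <= start < end <= self.chrom_length):
                raise ValueError(f"inversion interval {chrom}:{start}-{end} "
                                 "outside chromosome bounds")
        for eff in list(self.backcross_effects.values()) + [self.causal_effect]:
            if not np.isfinite(eff):
                raise ValueError("effect sizes must be finite")
        if self.bm_sigma2 < 0:
            raise ValueError("bm_sigma2 must be non-negative")

    def rng(self, tag: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2**31), tag])

    @property
    def chromosomes(self) -> list:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


# ---------------------------------------------------------------------------
# landmarks


@dataclass
class LandmarkSample:
    configs: list
    truth: dict


def _base_head_shape(n: int) -> np.ndarray:
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([np.cos(theta), 0.8 * np.sin(theta)])
    pts -= pts.mean(axis=0)
    return pts / np.sqrt((pts**2).sum())


def _similarity_basis(base: np.ndarray) -> np.ndarray:
    """Orthonormal translation/scale/rotation directions at the base shape."""
    n = base.shape[0]
    tx = np.tile([1.0, 0.0], n)
    ty = np.tile([0.0, 1.0], n)
    scale = base.reshape(-1).copy()
    rot = np.column_stack([-base[:, 1], base[:, 0]]).reshape(-1)
    basis = np.stack([tx, ty, scale, rot])
    q, _ = np.linalg.qr(basis.T)
    return q  # (2n, 4)


def _orthonormal_directions(rng, n_dims: int, n_dirs: int,
                            exclude: np.ndarray) -> list:
    """Random unit vectors orthogonal to `exclude` columns and to each other."""
    dirs = []
    taken = exclude.copy()
    for _ in range(n_dirs):
        v = rng.standard_normal(n_dims)
        v -= taken @ (taken.T @ v)
        for d in dirs:
            v -= d * (d @ v)
        v /= np.linalg.norm(v)
        dirs.append(v)
    return dirs


def gen_landmarks(cfg: SimConfig) -> LandmarkSample:
    """Landmark configurations with planted group means and nuisance fields.

    The pitch, biological and yaw deformation fields are fixed unit-norm
    vectors shared by all specimens (scores vary per specimen), mutually
    orthogonal, orthogonal to each group's mean-offset direction and to the
    local similarity directions (so alignment cannot absorb them).  The
    default amplitude ordering pitch > biological > yaw places pitch on PC1
    and yaw on PC3 of the raw pooled within-group PCA - and on PC2 after
    pitch has been removed, which is what the two-step correction expects.
    """
    if len(cfg.groups) < 2:
        raise ValueError("need at least 2 groups")
    if cfg.n_landmarks < 3:
        raise ValueError("need at least 3 landmarks")
    rng = cfg.rng(1)
    base = _base_head_shape(cfg.n_landmarks)
    p = 2 * cfg.n_landmarks
    sim = _similarity_basis(base)
    dirs = _orthonormal_directions(rng, p, len(cfg.groups) + 3, sim)
    group_dirs = dirs[: len(cfg.groups)]
    pitch_vec, bio_vec, yaw_vec = dirs[len(cfg.groups):]

    pitch_sd, yaw_sd = cfg.nuisance_amplitudes
    configs = []
    truth = {
        "pitch_vector": pitch_vec, "yaw_vector": yaw_vec, "bio_vector": bio_vec,
        "group_means": {}, "pitch_scores": [], "yaw_scores": [], "bio_scores": [],
        "specimen_groups": [],
    }
    for g, (label, n_spec, offset) in enumerate(cfg.groups):
        mean_flat = base.reshape(-1) + offset * group_dirs[g]
        truth["group_means"][label] = mean_flat.reshape(-1, 2)
        for i in range(n_spec):
            ps = rng.normal(0, pitch_sd) if pitch_sd > 0 else 0.0
            ys = rng.normal(0, yaw_sd) if yaw_sd > 0 else 0.0
            bs = rng.normal(0, cfg.bio_amplitude) if cfg.bio_amplitude > 0 else 0.0
            flat = mean_flat + ps * pitch_vec + ys * yaw_vec + bs * bio_vec
            if cfg.landmark_noise_sd > 0:
                flat = flat + rng.normal(0, cfg.landmark_noise_sd, p)
            shape = flat.reshape(-1, 2)
            angle = rng.uniform(0, 2 * np.pi)
            rot = np.array([[np.cos(angle), -np.sin(angle)],
                            [np.sin(angle), np.cos(angle)]])
            scale = rng.uniform(200, 400)      # pixel-scale digitization
            shift = rng.uniform(-50, 50, 2)
            coords = scale * shape @ rot.T + shift
            configs.append(LandmarkConfiguration(
                specimen_id=f"{label}_{i}", group=label, coords=coords))
            truth["pitch_scores"].append(ps)
            truth["yaw_scores"].append(ys)
            truth["bio_scores"].append(bs)
            truth["specimen_groups"].append(label)
    for key in ("pitch_scores", "yaw_scores", "bio_scores"):
        truth[key] = np.asarray(truth[key])
    return LandmarkSample(configs=configs, truth=truth)


# ---------------------------------------------------------------------------
# backcross


MARKERS = {"A6": "X", "B3": "c4", "C3": "c5", "C5": "c5", "D7": "c23", "E7": "c23"}
LINKED_PAIRS = [("C3", "C5"), ("D7", "E7")]


@dataclass
class BackcrossSample:
    genotypes: pd.DataFrame            # marker-level calls
    chromosome_genotypes: pd.DataFrame  # one call per chromosome
    phenotypes: pd.DataFrame
    truth: dict


def gen_backcross(cfg: SimConfig) -> BackcrossSample:
    """Backcross genotypes and phenotypes with planted chromosome effects.

    Chromosomes segregate independently, each hom/het with probability 1/2.
    Relative eye size carries additive per-chromosome effects (percent of
    the hom-class baseline); a latent body-size factor scales all organs
    (areas quadratically, lengths linearly) and is itself shifted by the
    chromosomes in ``backcross_body_effects`` (default: the 5th).  Linked
    marker pairs can disagree with probability ``recombinant_prob`` and
    individuals carry impossible donor-homozygote calls with probability
    ``contaminant_prob``, feeding the recombinant filter.
    """
    rng = cfg.rng(2)
    n = cfg.n_individuals_backcross
    chroms = list(cfg.backcross_effects)
    het = {c: rng.integers(0, 2, n).astype(bool) for c in chroms}

    z = rng.normal(0, 1, n)
    s = 1.0 + cfg.body_size_sd * z
    for c, eff in cfg.backcross_body_effects.items():
        s = s + eff * het[c].astype(float)

    # additive phenotype: baseline + chromosome effects + body-size channel
    # + noise; the body channel scales areas quadratically in s
    b = cfg.backcross_baseline_eye
    genetic = np.zeros(n)
    for c, eff in cfg.backcross_effects.items():
        genetic += eff * het[c].astype(float)
    noise = rng.normal(0, cfg.backcross_noise_frac, n)
    eye = b * (1.0 + genetic + noise) + b * (s**2 - 1.0)
    tib = {f"tibia{i + 1}": 700.0 * s * (1 + rng.normal(0, 0.01, n))
           for i in range(3)}
    wing = 2.2e6 * s**2 * (1 + rng.normal(0, 0.02, n))

    ids = [f"bc{i + 1}" for i in range(n)]
    geno = {"individual_id": ids}
    for marker, chrom in MARKERS.items():
        calls = np.where(het[chrom], bc.HET, bc.HOM).astype(object)
        geno[marker] = calls
    # recombinants: flip the second marker of a linked pair
    for first, second in LINKED_PAIRS:
        flip = rng.random(n) < cfg.recombinant_prob
        swapped = np.where(np.asarray(geno[second]) == bc.HET, bc.HOM, bc.HET)
        geno[second] = np.where(flip, swapped, geno[second]).astype(object)
    contaminated = rng.random(n) < cfg.contaminant_prob
    which = rng.choice(["A6", "E7"], n)
    for m in ("A6", "E7"):
        mask = contaminated & (which == m)
        geno[m] = np.where(mask, bc.IMPOSSIBLE, geno[m]).astype(object)

    genotypes = pd.DataFrame(geno)
    chrom_calls = pd.DataFrame({
        "individual_id": ids,
        **{c: np.where(het[c], bc.HET, bc.HOM) for c in chroms},
    })
    phenotypes = pd.DataFrame({
        "individual_id": ids, "group": "backcross",
        "eye_area": eye, "wing_area": wing, **tib,
    })
    truth = {
        "effects": dict(cfg.backcross_effects),
        "effect_coefficients": {c: b * e for c, e in cfg.backcross_effects.items()},
        "body_effects": dict(cfg.backcross_body_effects),
        "het": {c: het[c].copy() for c in chroms},
        "noise_frac": cfg.backcross_noise_frac,
        "linked_pairs": list(LINKED_PAIRS),
        "marker_chromosomes": dict(MARKERS),
        "n_recombinant": 0, "n_contaminant": int(contaminated.sum()),
    }
    return BackcrossSample(genotypes, chrom_calls, phenotypes, truth)


# ---------------------------------------------------------------------------
# pool-seq: F18 sib-mating with inversion recombination suppression

# A haplotype is (breaks, anc): segment i covers [breaks[i-1], breaks[i])
# with breaks[-1] == chromosome length; anc is founder index (0 = reference
# D. americana SF12 carrying the derived inversions' alternative... here 0
# simply marks the reference founder whose alleles are the `ref` calls).


def _founder(length: float, anc: int):
    return np.array([length]), np.array([anc], dtype=np.int8)


def _ancestry_at(hap, pos: np.ndarray) -> np.ndarray:
    breaks, anc = hap
    return anc[np.searchsorted(breaks, pos, side="right")]


def _gamete(h1, h2, length: float, rng, suppress: list,
            lam: float):
    """One meiotic product of a diploid (h1, h2) chromosome.

    ``suppress`` lists (start, end) intervals where crossovers are dropped
    (inversion heterokaryotype); Poisson(lam) crossovers otherwise.
    """
    k = rng.poisson(lam)
    cuts = np.sort(rng.uniform(0, length, k)) if k else np.empty(0)
    for s, e in suppress:
        cuts = cuts[(cuts < s) | (cuts > e)]
    haps = (h1, h2) if rng.random() < 0.5 else (h2, h1)
    if cuts.size == 0:
        return haps[0]
    bounds = np.concatenate([[0.0], cuts, [length]])
    new_breaks, new_anc = [], []
    for i in range(len(bounds) - 1):
        src = haps[i % 2]
        s, e = bounds[i], bounds[i + 1]
        breaks, anc = src
        lo = np.searchsorted(breaks, s, side="right")
        hi = np.searchsorted(breaks, e, side="left")
        seg_ends = np.append(breaks[lo:hi], e)
        seg_anc = anc[lo:hi + 1]
        for end, a in zip(seg_ends, seg_anc):
            if new_anc and new_anc[-1] == a:
                new_breaks[-1] = end
            else:
                new_breaks.append(end)
                new_anc.append(a)
    new_breaks[-1] = length
    return np.asarray(new_breaks), np.asarray(new_anc, dtype=np.int8)


def _hetero_intervals(ind_chrom, intervals) -> list:
    """Inversion intervals for which this diploid is heterokaryotypic."""
    h1, h2 = ind_chrom
    out = []
    for s, e in intervals:
        mid = np.array([(s + e) / 2.0])
        if _ancestry_at(h1, mid)[0] != _ancestry_at(h2, mid)[0]:
            out.append((s, e))
    return out


def _offspring(mother, father, cfg: SimConfig, rng, inv_by_chrom) -> dict:
    child = {}
    for chrom in cfg.chromosomes:
        length = cfg.chrom_length
        egg = _gamete(*mother[chrom], length, rng,
                      _hetero_intervals(mother[chrom], inv_by_chrom[chrom]),
                      cfg.crossovers_per_chrom)
        sperm = _gamete(*father[chrom], length, rng,
                        _hetero_intervals(father[chrom], inv_by_chrom[chrom]),
                        cfg.crossovers_per_chrom)
        child[chrom] = (egg, sperm)
    return child


@dataclass
class PoolseqSample:
    snps: pd.DataFrame
    truth: dict


def _snp_catalog(cfg: SimConfig) -> tuple[dict, np.ndarray, np.ndarray]:
    """Shared SNP site catalog: positions and ref/alt bases per chromosome.

    Drawn from a dedicated stream keyed only by the config seed, so the F18
    quartile pools and the population pools of the same configuration carry
    the same sites - as they would when called against one SNP table.
    """
    rng = cfg.rng(10)
    per = cfg.n_snps // cfg.n_chromosomes
    extra = cfg.n_snps - per * cfg.n_chromosomes
    out = {}
    for i, chrom in enumerate(cfg.chromosomes):
        m = per + (1 if i < extra else 0)
        pos = np.sort(rng.choice(
            np.arange(1, int(cfg.chrom_length)), size=m, replace=False))
        out[chrom] = pos
    bases = np.array(["A", "C", "G", "T"])
    total = sum(len(p) for p in out.values())
    ref_idx = rng.integers(0, 4, total)
    alt = bases[(ref_idx + 1 + rng.integers(0, 3, total)) % 4]
    return out, bases[ref_idx], alt


def gen_poolseq(cfg: SimConfig) -> PoolseqSample:
    """F18 quartile pools from brother-sister mating with inversions.

    One F1 pair (founders fixed for alternative alleles at every SNP)
    founds ``n_lines`` full-sib chains; after ``n_generations`` meiotic
    generations the phenotyped females are fresh progeny drawn round-robin
    across chains.  Phenotype = additive causal-SNP dosage effects + noise;
    females are ranked and pooled by :func:`eyemorph.poolgwas.quartile_partition`;
    read counts are Binomial(depth, pool allele frequency) with
    depth ~ round(Normal(coverage_mean, coverage_sd)) truncated at 1.
    """
    rng = cfg.rng(3)
    snp_pos, ref, alt = _snp_catalog(cfg)
    inv_by_chrom = {c: [] for c in cfg.chromosomes}
    for chrom, s, e in cfg.inversion_intervals:
        if chrom not in inv_by_chrom:
            raise ValueError(f"inversion on unknown chromosome {chrom}")
        inv_by_chrom[chrom].append((float(s), float(e)))

    # causal SNPs
    causal = []   # (chrom, pos) drawn from the SNP grid
    if cfg.n_causal_snps > 0:
        if cfg.causal_inside_inversion and cfg.inversion_intervals:
            chrom, s, e = cfg.inversion_intervals[0]
            inside = snp_pos[chrom][(snp_pos[chrom] >= s) & (snp_pos[chrom] <= e)]
            if inside.size < cfg.n_causal_snps:
                raise ValueError("causal SNP outside simulated genome: "
                                 "not enough SNPs inside the inversion interval")
            picks = rng.choice(inside, cfg.n_causal_snps, replace=False)
            causal = [(chrom, int(p)) for p in picks]
        else:
            for _ in range(cfg.n_causal_snps):
                chrom = cfg.chromosomes[rng.integers(cfg.n_chromosomes)]
                causal.append((chrom, int(rng.choice(snp_pos[chrom]))))

    # founders and F1 pair (every F1 is reference/alternative heterozygous)
    length = cfg.chrom_length

    def _f1() -> dict:
        return {c: (_founder(length, 0), _founder(length, 1))
                for c in cfg.chromosomes}

    f1_pair = (_f1(), _f1())

    # full-sib chains: each generation, the pair is replaced by two of its
    # own offspring (a brother and a sister)
    finals = []
    for _ in range(cfg.n_lines):
        pair = f1_pair
        for _ in range(cfg.n_generations - 1):
            mother, father = pair
            pair = (_offspring(mother, father, cfg, rng, inv_by_chrom),
                    _offspring(mother, father, cfg, rng, inv_by_chrom))
        finals.append(pair)

    # F18 pooled females, round-robin across chains
    individuals = []
    line_of = []
    for i in range(cfg.n_individuals_pool):
        line = i % cfg.n_lines
        mother, father = finals[line]
        individuals.append(_offspring(mother, father, cfg, rng, inv_by_chrom))
        line_of.append(line)

    # reference-allele (founder 0) dosage matrix: individuals x snps
    dosage_cols = []
    chrom_col, pos_col = [], []
    for chrom in cfg.chromosomes:
        pos = snp_pos[chrom].astype(float)
        dos = np.zeros((len(individuals), pos.size), dtype=np.int8)
        for j, ind in enumerate(individuals):
            h1, h2 = ind[chrom]
            dos[j] = (_ancestry_at(h1, pos) == 0).astype(np.int8) + \
                     (_ancestry_at(h2, pos) == 0).astype(np.int8)
        dosage_cols.append(dos)
        chrom_col.extend([chrom] * pos.size)
        pos_col.extend(snp_pos[chrom].tolist())
    dosage = np.concatenate(dosage_cols, axis=1)

    # phenotype from causal dosages
    pheno = rng.normal(0, cfg.poolseq_noise_sd, len(individuals)) \
        if cfg.poolseq_noise_sd > 0 else np.zeros(len(individuals))
    key = {(c, p): i for i, (c, p) in enumerate(zip(chrom_col, pos_col))}
    for chrom, p in causal:
        pheno = pheno + cfg.causal_effect * dosage[:, key[(chrom, p)]]

    quartiles = poolgwas.quartile_partition(pheno)
    pools = ["Q1", "Q2", "Q3", "Q4"]
    data = {"chrom": chrom_col, "pos": pos_col, "ref": ref, "alt": alt}
    true_counts = {}
    pop_count = dosage.sum(axis=0)
    pop_total = 2 * len(individuals)
    for q, members in zip(pools, quartiles):
        if cfg.null_common_pools:
            count_ref, total = pop_count, pop_total
        else:
            count_ref = dosage[members].sum(axis=0)
            total = 2 * len(members)
        true_counts[q] = (count_ref.copy(), total)
        depth = np.maximum(
            np.rint(rng.normal(cfg.coverage_mean, cfg.coverage_sd, len(chrom_col))),
            1).astype(np.int64)
        reads_ref = rng.binomial(depth, count_ref / total)
        data[f"{q}_ref"] = reads_ref
        data[f"{q}_alt"] = depth - reads_ref
    snps = pd.DataFrame(data)
    truth = {
        "causal": causal, "phenotype": pheno, "quartiles": quartiles,
        "true_pool_counts": true_counts, "line_of": np.asarray(line_of),
        "inversion_intervals": list(cfg.inversion_intervals),
        "snp_positions": snp_pos, "dosage": dosage,
    }
    return PoolseqSample(snps=snps, truth=truth)


# ---------------------------------------------------------------------------
# population pools


@dataclass
class PopulationPoolSample:
    snps: pd.DataFrame
    truth: dict


def gen_population_pools(cfg: SimConfig) -> PopulationPoolSample:
    """Two population pools differentiated only inside inversion intervals."""
    rng = cfg.rng(4)
    snp_pos, ref, alt = _snp_catalog(cfg)
    chrom_col, pos_col, inside = [], [], []
    for chrom in cfg.chromosomes:
        pos = snp_pos[chrom]
        mask = np.zeros(pos.size, dtype=bool)
        for c, s, e in cfg.inversion_intervals:
            if c == chrom:
                mask |= (pos >= s) & (pos <= e)
        chrom_col.extend([chrom] * pos.size)
        pos_col.extend(pos.tolist())
        inside.extend(mask.tolist())
    inside = np.asarray(inside)
    m = len(chrom_col)
    p_south = np.where(inside, cfg.pop_freq_inside[0], cfg.pop_freq_outside)
    p_north = np.where(inside, cfg.pop_freq_inside[1], cfg.pop_freq_outside)
    data = {"chrom": chrom_col, "pos": pos_col, "ref": ref, "alt": alt}
    n2 = 2 * cfg.n_individuals_per_population
    for pool, p in (("south", p_south), ("north", p_north)):
        alleles_ref = rng.binomial(n2, p)
        depth = np.maximum(
            np.rint(rng.normal(cfg.coverage_mean, cfg.coverage_sd, m)), 1
        ).astype(np.int64)
        reads_ref = rng.binomial(depth, alleles_ref / n2)
        data[f"{pool}_ref"] = reads_ref
        data[f"{pool}_alt"] = depth - reads_ref
    snps = pd.DataFrame(data)
    return PopulationPoolSample(snps=snps, truth={"differentiated": inside})


# ---------------------------------------------------------------------------
# tree traits


def gen_tree_traits(cfg: SimConfig) -> tuple[TraitTree, dict]:
    """Brownian-motion tip traits on the configured tree from a known root."""
    rng = cfg.rng(5)
    tree = dendropy.Tree.get(data=cfg.tree_newick, schema="newick")
    states = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            states[id(node)] = float(cfg.bm_root_state)
            continue
        bl = node.edge.length if node.edge.length is not None else 0.0
        if bl < 0:
            raise ValueError("negative branch length")
        step = rng.normal(0, math.sqrt(cfg.bm_sigma2 * bl)) \
            if cfg.bm_sigma2 > 0 and bl > 0 else 0.0
        states[id(node)] = states[id(node.parent_node)] + step
    traits = {lf.taxon.label: states[id(lf)] for lf in tree.leaf_node_iter()}
    tt = TraitTree(tree=tree, traits=traits)
    return tt, {"root_state": float(cfg.bm_root_state), "sigma2": cfg.bm_sigma2}
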