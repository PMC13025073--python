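"""Branching-process tumor simulator with binomial sequencing emulation.

Generates synthetic tumors under the two-population model of
:mod:`cloneclock.growth`: a discrete-time branching process with per-daughter
death, per-division mutation influx, and a single advantaged subclone seeded
by one converting cell.  Because a tumor sampled late is astronomically
large, the simulation is hybrid:

1. **Exact phase** — every cell is simulated individually (offspring counts,
   deaths, Poisson mutation influx, full genealogy) while the population is
   at most ``cutover_size``;
2. **Deterministic phase** — beyond the handoff, each clone and every
   existing mutation cohort is expanded deterministically at its clone's
   exponential rate, and post-handoff mutation cohorts are added along the
   representative lineages with their expected cell fractions.

The sampling generation ``te`` is solved from the *realized* clone census so
that the realized subclone fraction equals the drawn target exactly; the
returned ground truth therefore reflects the stochastic trajectory that was
actually simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth import EvolutionParams, MutationClass, net_growth_rate

__all__ = [
    "SimulationConfig",
    "TumorTruth",
    "LineageExtinctionError",
    "UnreachableTargetError",
    "simulate_lineage",
    "sequence_tumor",
    "generate_benchmark_suite",
    "write_variants_tsv",
    "write_truth_tsv",
    "write_vcf",
]

_BASES = np.array(list("ACGT"))


class LineageExtinctionError(RuntimeError):
    """The branching process died out repeatedly before the tumor formed."""


class UnreachableTargetError(RuntimeError):
    """The drawn (tf, s) cannot realize the requested subclone fraction."""


@dataclass
class SimulationConfig:
    """Benchmark simulation conditions.

    Defaults reproduce the reference benchmark: mutation rate 16 per diploid
    genome per division, death rate 0.2, 120x sequencing depth, emergence
    time drawn from [4, 14] generations, selection coefficient from
    [0.125, 1.625] and target subclone fraction from [0, 0.97].
    """

    mu: float = 16.0
    death_rate: float = 0.2
    s_range: tuple[float, float] = (0.125, 1.625)
    tf_range: tuple[int, int] = (4, 14)
    p_range: tuple[float, float] = (0.0, 0.97)
    depth: int = 120
    purity: float = 1.0
    #: number of clonal mutations preexisting in the founder cell
    n_root: int = 50
    #: population size at which the exact phase hands off to deterministic growth
    cutover_size: int = 10_000
    #: mutations with true cell fraction below this are dropped (with a count)
    fraction_floor: float = 1e-4
    #: if True, every site is sequenced at exactly ``depth`` (no Poisson jitter)
    fixed_depth: bool = False
    #: explicit sampling generation; when None, te is solved from the target
    #: tumor size (or from a target P when one is passed to simulate_lineage)
    te: float | None = None
    #: tumor cell count at sampling; the benchmark holds this constant and
    #: lets the realized subclone fraction fall where the competition puts it
    target_size: float = 1e8
    max_retries: int = 25

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0 < self.purity <= 1:
            raise ValueError("purity must lie in (0, 1]")
        net_growth_rate(self.death_rate)  # domain check


@dataclass
class TumorTruth:
    """Ground truth of one simulated tumor.

    ``mutations`` has one row per retained mutation: ``mutation_id``,
    ``mutation_class``, ``generation`` (acquisition time) and
    ``cell_fraction`` (realized fraction of tumor cells carrying it at te).
    """

    params: EvolutionParams
    mutations: pd.DataFrame
    n_dropped: int = 0
    handoff_generation: int = 0
    ka_census: np.ndarray = field(default_factory=lambda: np.zeros(0))
    kf_census: np.ndarray = field(default_factory=lambda: np.zeros(0))
    n_attempts: int = 1


# ---------------------------------------------------------------------------
# Exact branching phase
# ---------------------------------------------------------------------------

def _run_exact_phase(rng, config: SimulationConfig, s: float, tf_seed: int):
    """Simulate every cell until the population exceeds the cutover size.

    Returns per-generation parent/clone arrays, the clone census, and the
    index of the MRCAf cell at its seeding generation.  Raises
    :class:`LineageExtinctionError` on whole-population or subclone
    extinction (the caller retries with a fresh sub-seed).
    """
    beta = config.death_rate
    m_f = (2.0 * (1.0 - beta)) ** (1.0 + s)  # expected surviving Kf offspring
    parents: list[np.ndarray] = [np.zeros(0, dtype=np.int64)]  # gen 0 placeholder
    clones: list[np.ndarray] = [np.zeros(1, dtype=bool)]
    ka_census = [1]
    kf_census = [0]
    mrcaf_index: int | None = None
    cur_clone = clones[0]
    g = 0
    # stop only once the population is past cutover AND the subclone exists
    while True:
        g += 1
        n = cur_clone.size
        n_off = np.empty(n, dtype=np.int64)
        ka_mask = ~cur_clone
        n_ka = int(ka_mask.sum())
        if n_ka:
            n_off[ka_mask] = rng.binomial(2, 1.0 - beta, size=n_ka)
        if n - n_ka:
            n_off[cur_clone] = rng.poisson(m_f, size=n - n_ka)
        parent_idx = np.repeat(np.arange(n), n_off)
        if parent_idx.size == 0:
            raise LineageExtinctionError(f"population extinct at generation {g}")
        new_clone = cur_clone[parent_idx].copy()
        if s > 0 and g == tf_seed:
            ka_children = np.flatnonzero(~new_clone)
            if ka_children.size == 0:
                raise LineageExtinctionError("no ancestral cell available at tf")
            mrcaf_index = int(rng.choice(ka_children))
            new_clone[mrcaf_index] = True
        parents.append(parent_idx)
        clones.append(new_clone)
        kf = int(new_clone.sum())
        ka_census.append(parent_idx.size - kf)
        kf_census.append(kf)
        cur_clone = new_clone
        if s > 0 and g > tf_seed and kf == 0:
            raise LineageExtinctionError(f"subclone extinct at generation {g}")
        done = parent_idx.size > config.cutover_size and (s == 0 or g >= tf_seed)
        if done:
            break
        if parent_idx.size > max(50 * config.cutover_size, 2_000_000):
            raise RuntimeError(
                "population exploded before reaching the seeding generation; "
                "cutover_size is too small for this tf"
            )
        if g > 500:
            raise RuntimeError("exceeded 500 generations in the exact phase")
    return parents, clones, np.array(ka_census), np.array(kf_census), mrcaf_index


def _solve_te_from_size(ka_h, kf_h, h, lam, s, target_size):
    """Sampling generation at which the tumor census reaches target_size."""
    if ka_h + kf_h >= target_size:
        return float(h)
    m_f = lam * (1.0 + s)
    if kf_h == 0:
        return h + math.log(target_size / ka_h) / lam
    from scipy.optimize import brentq

    hi = math.log(target_size / min(ka_h + kf_h, target_size)) / lam + 1.0

    def census(delta):
        return ka_h * math.exp(lam * delta) + kf_h * math.exp(m_f * delta) - target_size

    return h + brentq(census, 0.0, hi, xtol=1e-10)


def _solve_te_from_census(ka, kf, tf_seed, lam, s, target_p):
    """Choose (handoff generation, te) so the realized P at te equals target_p.

    Scans the realized census for the latest generation whose clone odds are
    still at or below the target odds and extrapolates deterministically
    from there.
    """
    if not 0.0 < target_p < 1.0:
        raise UnreachableTargetError(f"target P={target_p} has no finite odds")
    omega = target_p / (1.0 - target_p)
    last = len(ka) - 1
    best = None
    for g in range(tf_seed, last + 1):
        if kf[g] > 0 and ka[g] > 0 and kf[g] / ka[g] <= omega:
            best = g
    if best is None:
        raise UnreachableTargetError(
            f"realized subclone odds already exceed target P={target_p} at emergence"
        )
    odds = kf[best] / ka[best]
    delta = math.log(omega / odds) / (lam * s)
    # the target can be hit exactly at emergence; keep te strictly after tf
    return best, max(best + delta, tf_seed + 1e-6)


def _descendant_counts(parents, clones, h):
    """Per-cell descendant counts, split by clone, measured at generation h."""
    dka = [None] * (h + 1)
    dkf = [None] * (h + 1)
    dka[h] = (~clones[h]).astype(float)
    dkf[h] = clones[h].astype(float)
    for g in range(h, 0, -1):
        n_prev = clones[g - 1].size
        dka[g - 1] = np.bincount(parents[g], weights=dka[g], minlength=n_prev)
        dkf[g - 1] = np.bincount(parents[g], weights=dkf[g], minlength=n_prev)
    return dka, dkf


def _foundation_path(parents, mrcaf_index, tf_seed):
    """Index of the foundation-lineage cell at each generation 1..tf_seed."""
    path = {tf_seed: mrcaf_index}
    idx = mrcaf_index
    for g in range(tf_seed, 1, -1):
        idx = int(parents[g][idx])
        path[g - 1] = idx
    return path


def simulate_lineage(
    config: SimulationConfig,
    seed: int,
    tf: float | None = None,
    s: float | None = None,
    target_p: float | None = None,
) -> TumorTruth:
    """Simulate one tumor and return its ground truth.

    ``tf``, ``s`` and ``target_p`` override the config ranges when given
    (the benchmark generator draws them and passes them in).  The lineage is
    retried with an incremented sub-seed if it goes extinct, up to
    ``config.max_retries``.
    """
    draw_rng = np.random.default_rng([int(seed), 0xD12A])
    if tf is None:
        tf = int(draw_rng.integers(config.tf_range[0], config.tf_range[1] + 1))
    if s is None:
        s = float(draw_rng.uniform(*config.s_range))
    if s > 0 and target_p is None and config.te is None and config.target_size is None:
        target_p = float(draw_rng.uniform(*config.p_range))
    tf_seed = int(math.floor(tf))
    if tf_seed < 1:
        raise ValueError("tf must be >= 1 generation")
    lam = net_growth_rate(config.death_rate)

    last_err: Exception | None = None
    for attempt in range(config.max_retries):
        rng = np.random.default_rng([int(seed), 1 + attempt])
        try:
            parents, clones, ka, kf, mrcaf_index = _run_exact_phase(
                rng, config, s, tf_seed
            )
        except LineageExtinctionError as err:
            last_err = err
            continue
        return _assemble_truth(
            rng, config, parents, clones, ka, kf, mrcaf_index,
            lam, s, tf_seed, target_p, attempt + 1,
        )
    raise LineageExtinctionError(
        f"lineage extinct in all {config.max_retries} attempts: {last_err}"
    )


def _assemble_truth(
    rng, config, parents, clones, ka, kf, mrcaf_index,
    lam, s, tf_seed, target_p, n_attempts,
) -> TumorTruth:
    last = len(ka) - 1
    if config.te is not None:
        te = float(config.te)
        if s > 0 and te <= tf_seed:
            raise ValueError(f"config.te={te} must exceed tf={tf_seed}")
        h = min(last, int(math.floor(te)))
        if s > 0:
            h = max(h, tf_seed)
    elif target_p is not None and s > 0:
        h, te = _solve_te_from_census(ka, kf, tf_seed, lam, s, target_p)
    elif config.target_size is not None:
        h = last
        te = _solve_te_from_size(float(ka[h]), float(kf[h]), h, lam, s, config.target_size)
    elif s == 0:
        te = float(last)
        h = last
    else:
        raise ValueError("need one of config.te, config.target_size or target_p")

    ka_h, kf_h = float(ka[h]), float(kf[h])
    # relative per-cell weights of Ka vs Kf descendants at te, factored to
    # avoid overflow for large te - h
    if kf_h > 0:
        r = math.exp(-lam * s * (te - h))
        denom = ka_h * r + kf_h
        w_ka, w_kf = r, 1.0
    else:
        denom = ka_h
        w_ka, w_kf = 1.0, 0.0
    p_realized = (kf_h * w_kf) / denom if kf_h > 0 else 0.0

    dka, dkf = _descendant_counts(parents, clones, h)
    path = (
        _foundation_path(parents, mrcaf_index, tf_seed)
        if (s > 0 and mrcaf_index is not None)
        else {}
    )

    frac_chunks: list[np.ndarray] = []
    gen_chunks: list[np.ndarray] = []
    class_chunks: list[np.ndarray] = []
    n_dropped = 0

    # root mutations: preexist in the founder, fraction exactly 1
    frac_chunks.append(np.ones(config.n_root))
    gen_chunks.append(np.zeros(config.n_root))
    class_chunks.append(np.full(config.n_root, MutationClass.ROOT.value, dtype=object))

    for g in range(1, h + 1):
        n_cells = clones[g].size
        counts = rng.poisson(config.mu, size=n_cells)
        frac = (dka[g] * w_ka + dkf[g] * w_kf) / denom
        labels = np.full(n_cells, MutationClass.INCIDENTAL.value, dtype=object)
        if s > 0 and path:
            if g < tf_seed:
                labels[path[g]] = MutationClass.TRUNK.value
            elif g == tf_seed:
                labels[mrcaf_index] = MutationClass.BRANCH.value
            if g > tf_seed:
                labels[clones[g]] = MutationClass.SUCCESSIVE.value
        keep = frac >= config.fraction_floor
        n_dropped += int(counts[~keep].sum())
        idx = np.flatnonzero(keep)
        if idx.size:
            rep = counts[idx]
            frac_chunks.append(np.repeat(frac[idx], rep))
            gen_chunks.append(np.full(int(rep.sum()), float(g)))
            class_chunks.append(np.repeat(labels[idx], rep))

    # deterministic-phase cohorts along the representative lineages
    for t in range(h + 1, int(math.floor(te)) + 1):
        new = []
        if kf_h > 0:
            f_succ = (p_realized / kf_h) * math.exp(-lam * (1.0 + s) * (t - h))
            if f_succ >= config.fraction_floor:
                new.append((f_succ, MutationClass.SUCCESSIVE.value))
        f_inc = ((1.0 - p_realized) / ka_h) * math.exp(-lam * (t - h)) if ka_h > 0 else 0.0
        if f_inc >= config.fraction_floor:
            new.append((f_inc, MutationClass.INCIDENTAL.value))
        if not new:
            break
        for f, label in new:
            n_new = int(rng.poisson(config.mu))
            if n_new:
                frac_chunks.append(np.full(n_new, f))
                gen_chunks.append(np.full(n_new, float(t)))
                class_chunks.append(np.full(n_new, label, dtype=object))

    mutations = pd.DataFrame(
        {
            "mutation_class": np.concatenate(class_chunks),
            "generation": np.concatenate(gen_chunks),
            "cell_fraction": np.concatenate(frac_chunks),
        }
    )
    mutations.insert(0, "mutation_id", np.arange(len(mutations)))

    params = EvolutionParams(
        mu=config.mu,
        s=float(s),
        tf=float(tf_seed) if s > 0 else None,
        te=float(te),
        death_rate=config.death_rate,
        P=float(p_realized),
    )
    return TumorTruth(
        params=params,
        mutations=mutations,
        n_dropped=n_dropped,
        handoff_generation=h,
        ka_census=ka,
        kf_census=kf,
        n_attempts=n_attempts,
    )


# ---------------------------------------------------------------------------
# Sequencing emulation
# ---------------------------------------------------------------------------

def sequence_tumor(
    truth: TumorTruth,
    depth: int,
    purity: float = 1.0,
    seed: int = 0,
    fixed_depth: bool = False,
) -> pd.DataFrame:
    """Emulate bulk sequencing of a simulated tumor.

    For a heterozygous mutation in a diploid region the expected VAF is half
    the fraction of cells carrying it, scaled by sample purity.  Per-site
    depth is Poisson around the nominal value (minimum 1 read) unless
    ``fixed_depth`` is set; alt reads are Binomial(depth, purity * f / 2).
    Sites drawing zero alt reads are retained with VAF 0 (minimum-support
    filtering is a preprocessing concern).

    Returns a variant table with synthetic coordinates: ``chrom``, ``pos``,
    ``ref``, ``alt``, ``depth``, ``alt_reads``, ``vaf``, plus the
    ``mutation_id`` linking back to the truth.
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must lie in (0, 1], got {purity}")
    f = truth.mutations["cell_fraction"].to_numpy()
    if f.size and (f.min() < 0 or f.max() > 1):
        raise ValueError("truth cell fractions must lie in [0, 1]")
    rng = np.random.default_rng([int(seed), 0x5E0])
    n = f.size
    if fixed_depth:
        d = np.full(n, int(depth), dtype=np.int64)
    else:
        d = np.maximum(rng.poisson(depth, size=n), 1)
    p = np.clip(purity * f / 2.0, 0.0, 1.0)
    alt = rng.binomial(d, p)
    ref_base = _BASES[rng.integers(0, 4, size=n)]
    alt_base = _BASES[(np.char.find("ACGT", ref_base.astype(str)) + rng.integers(1, 4, size=n)) % 4]
    return pd.DataFrame(
        {
            "mutation_id": truth.mutations["mutation_id"].to_numpy(),
            "chrom": "1",
            "pos": np.arange(1, n + 1) * 100,
            "ref": ref_base.astype(str),
            "alt": alt_base.astype(str),
            "depth": d,
            "alt_reads": alt,
            "vaf": np.where(d > 0, alt / d, 0.0),
        }
    )


# ---------------------------------------------------------------------------
# Benchmark suite
# ---------------------------------------------------------------------------

def generate_benchmark_suite(
    n_tumors: int,
    config: SimulationConfig | None = None,
    seed: int = 0,
    out_dir=None,
):
    """Generate a suite of benchmark tumors with paired truth and read counts.

    Draws (tf, s) uniformly from the config ranges and grows each tumor to
    the fixed target size (``config.target_size``); the realized subclone
    fraction falls where the clonal competition puts it, and draws whose
    realized fraction lands outside ``config.p_range`` are redrawn (counted
    in ``manifest.attrs['n_redraws']``), so the suite spans exactly the
    stated fraction range.  With ``config.target_size=None`` a target
    fraction is drawn instead and te solved from it.  Returns
    ``(tumors, manifest)`` where ``tumors`` is a list of
    ``(TumorTruth, reads DataFrame)`` and ``manifest`` one row of true
    parameters per tumor.  When ``out_dir`` is given, variants, truth and
    manifest are written there as tab-separated text.
    """
    if n_tumors < 1:
        raise ValueError("n_tumors must be >= 1")
    config = config or SimulationConfig()
    master = np.random.default_rng([int(seed), 0xBE9C])
    tumors = []
    rows = []
    n_redraws = 0
    for i in range(n_tumors):
        while True:
            sub_seed = int(master.integers(0, 2**31 - 1))
            tf = int(master.integers(config.tf_range[0], config.tf_range[1] + 1))
            s = float(master.uniform(*config.s_range))
            target_p = (
                float(master.uniform(*config.p_range))
                if config.target_size is None and config.te is None
                else None
            )
            try:
                truth = simulate_lineage(config, sub_seed, tf=tf, s=s, target_p=target_p)
            except (UnreachableTargetError, LineageExtinctionError):
                n_redraws += 1
                if n_redraws > 200 * n_tumors:
                    raise
                continue
            p_lo, p_hi = config.p_range
            if target_p is None and not p_lo <= truth.params.P <= p_hi:
                n_redraws += 1
                if n_redraws > 200 * n_tumors:
                    raise RuntimeError("too many redraws: realized P outside range")
                continue
            break
        reads = sequence_tumor(
            truth, config.depth, config.purity,
            seed=sub_seed, fixed_depth=config.fixed_depth,
        )
        tumors.append((truth, reads))
        rows.append(
            {
                "tumor_id": f"sim{i:04d}",
                "seed": sub_seed,
                "mu": truth.params.mu,
                "death_rate": config.death_rate,
                "s": truth.params.s,
                "tf": truth.params.tf,
                "te": truth.params.te,
                "P": truth.params.P,
                "n_mutations": len(truth.mutations),
                "n_dropped": truth.n_dropped,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.attrs["n_redraws"] = n_redraws
    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for row, (truth, reads) in zip(rows, tumors):
            write_variants_tsv(reads, out / f"{row['tumor_id']}.variants.tsv")
            write_truth_tsv(truth, out / f"{row['tumor_id']}.truth.tsv")
        manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return tumors, manifest


# ---------------------------------------------------------------------------
# Writers (tab-separated text and minimal VCF 4.2)
# ---------------------------------------------------------------------------

def write_variants_tsv(reads: pd.DataFrame, path) -> None:
    cols = ["chrom", "pos", "ref", "alt", "depth", "alt_reads"]
    reads[cols].to_csv(path, sep="\t", index=False)


def write_truth_tsv(truth: TumorTruth, path) -> None:
    truth.mutations.to_csv(path, sep="\t", index=False)


def write_vcf(reads: pd.DataFrame, path, sample: str = "TUMOR") -> None:
    """Write read counts as a minimal well-formed VCF 4.2 with DP/AD fields."""
    import pysam

    header = pysam.VariantHeader()
    max_pos = int(reads["pos"].max()) if len(reads) else 1
    for chrom in pd.unique(reads["chrom"]).astype(str):
        header.contigs.add(chrom, length=max_pos + 1000)
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for row in reads.itertuples(index=False):
            rec = vf.new_record(
                contig=str(row.chrom),
                start=int(row.pos) - 1,
                alleles=(row.ref, row.alt),
            )
            rec.samples[sample]["DP"] = int(row.depth)
            rec.samples[sample]["AD"] = (int(row.depth) - int(row.alt_reads), int(row.alt_reads))
            vf.write(rec)
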