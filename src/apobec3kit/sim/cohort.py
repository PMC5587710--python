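"""Cohort-level simulators: genotypes, exome depth, RNA-Seq reads,
mutation catalogs and survival outcomes, all with recorded ground truth.

One root seed drives everything; each stage derives its own child
generator from the root seed and a stage tag, so adding or reordering
stages never perturbs the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .locus import LocusModel, LocusParams, build_locus_model, random_dna, revcomp

_COMPL = {"A": "T", "C": "G", "G": "C", "T": "A"}

GENOTYPE_LABELS = {0: "A3B+/+", 1: "A3B+/-", 2: "A3B-/-"}


def child_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from the root seed."""
    key = zlib.crc32(stage.encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))


@dataclass
class ExpressionParams:
    """Baseline molar abundances and tumor fold-changes.

    A3A and the fusion transcript A3A_B share the A3A promoter, so both
    scale with the tumor fold of A3A; the fold defaults mirror the
    tumor/normal changes this kind of cohort shows for A3A (~8x) and A3B
    (~3x).  Per-haplotype dosage: A3A and A3B come from the non-deleted
    haplotype (2 - c copies), A3A_B from the deletion haplotype (c
    copies), where c counts deletion alleles.
    """

    base_molar: dict = field(
        default_factory=lambda: {"A3A": 30.0, "A3B": 20.0, "HK1": 100.0, "HK2": 100.0}
    )
    tumor_fold: dict = field(default_factory=lambda: {"A3A": 8.3, "A3B": 3.2})

    def sample_abundances(self, c: int, tissue: str) -> dict[str, float]:
        if c not in (0, 1, 2):
            raise ValueError(f"genotype must be 0, 1 or 2 deletion alleles, got {c}")
        fold_a = self.tumor_fold.get("A3A", 1.0) if tissue == "tumor" else 1.0
        fold_b = self.tumor_fold.get("A3B", 1.0) if tissue == "tumor" else 1.0
        ab = {
            "A3A": self.base_molar["A3A"] * (2 - c) / 2 * fold_a,
            "A3B": self.base_molar["A3B"] * (2 - c) / 2 * fold_b,
            "A3A_B": self.base_molar["A3A"] * c / 2 * fold_a,
        }
        for tx, v in self.base_molar.items():
            if tx not in ("A3A", "A3B"):
                ab[tx] = v
        return ab


@dataclass
class SurvivalParams:
    """Exponential proportional-hazards generator with independent censoring.

    ``baseline_hazard`` is in events per month; ``hazard_ratios`` maps a
    group label to its multiplicative hazard; ``censoring_rate`` is the
    target probability that a subject is censored before its event
    (achieved with a group-matched exponential censoring time);
    ``max_followup`` administratively censors at that many months.
    """

    baseline_hazard: float = 0.012
    hazard_ratios: dict = field(default_factory=lambda: {"low": 1.0, "high": 0.5})
    censoring_rate: float = 0.3
    max_followup: float = 120.0


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults follow the motivating scenario: a deletion-allele frequency
    near 0.5 (as in the Taiwanese OSCC population), 100x mean exome
    depth, 151-bp single-end RNA-Seq reads, a mutation mixture of
    APOBEC/aging/smoking-like signatures at 40/37/23% of the burden, and
    70% of APOBEC-context mutations in the A3A-like YTCA context.
    """

    n_samples: int = 200
    deletion_allele_freq: float = 0.5
    mean_depth: float = 100.0
    depth_dispersion: float = 2.0  # variance/mean of the depth model
    depth_noise_floor: float = 0.02  # off-target floor for homozygous deletions
    read_length: int = 151
    rnaseq_error_rate: float = 0.002
    n_reads_per_library: int = 6000
    mutations_per_sample: int = 120
    signature_weights: dict = field(
        default_factory=lambda: {
            "SBS2like": 0.20,
            "SBS13like": 0.20,
            "SBS1Alike": 0.185,
            "SBS1Blike": 0.185,
            "SBS5like": 0.23,
        }
    )
    yt_fraction_true: float = 0.7
    # per-sample signature weights ~ Dirichlet(weights * concentration):
    # cohorts are heterogeneous in aetiology, and NMF can only separate
    # signatures whose exposures vary across samples
    exposure_concentration: float = 8.0
    context_genome_len: int = 40000
    expression: ExpressionParams = field(default_factory=ExpressionParams)
    survival: SurvivalParams = field(default_factory=SurvivalParams)
    locus: LocusParams = field(default_factory=LocusParams)
    seed: int = 0

    def __post_init__(self):
        for name, p in [
            ("deletion_allele_freq", self.deletion_allele_freq),
            ("rnaseq_error_rate", self.rnaseq_error_rate),
            ("yt_fraction_true", self.yt_fraction_true),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if any(w < 0 for w in self.signature_weights.values()):
            raise ValueError("signature weights must be nonnegative")


def simulate_genotypes(n: int, q: float, seed: int | np.random.Generator) -> np.ndarray:
    """Hardy-Weinberg genotypes: copies of the deletion allele per sample.

    P(c=2) = q^2, P(c=1) = 2q(1-q), P(c=0) = (1-q)^2.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"allele frequency q={q} outside [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else child_rng(seed, "genotypes")
    return rng.binomial(2, q, size=int(n)).astype(np.int64)


def simulate_wes_depth(
    genotypes: np.ndarray,
    mean_depth: float,
    dispersion: float,
    seed: int | np.random.Generator,
    noise_floor: float = 0.02,
    sample_ids: list[str] | None = None,
    n_windows_inside: int = 25,
    n_windows_outside: int = 50,
) -> pd.DataFrame:
    """Per-sample mean depth inside the deletion region and in control regions.

    Per-window depth is gamma-Poisson (negative binomial) with
    ``dispersion`` the variance/mean ratio (``dispersion <= 1``
    degenerates to pure Poisson); the reported value is the mean over
    the region's windows, since a depth ratio over a multi-kilobase
    region averages away most single-site noise.  The inside-region mean
    is ``mean_depth * max((2 - c)/2, noise_floor)``: proportional to the
    retained copy number, floored at the off-target noise level so
    homozygous deletions keep a small nonzero depth.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else child_rng(seed, "wes_depth")
    c = np.asarray(genotypes)
    n = len(c)
    means_in = mean_depth * np.maximum((2 - c) / 2.0, noise_floor)
    means_out = np.full(n, float(mean_depth))

    def draw(mu, n_windows):
        mu = np.broadcast_to(mu[:, None], (n, n_windows))
        if dispersion <= 1.0:
            lam = mu
        else:
            shape = mu / (dispersion - 1.0)
            lam = rng.gamma(shape, dispersion - 1.0)
        return rng.poisson(lam).mean(axis=1)

    ids = sample_ids if sample_ids is not None else [f"S{i:04d}" for i in range(n)]
    return pd.DataFrame(
        {
            "sample": ids,
            "genotype_true": c,
            "depth_inside": draw(means_in, n_windows_inside),
            "depth_outside": draw(means_out, n_windows_outside),
        }
    )


def simulate_rnaseq_reads(
    locus_model: LocusModel,
    genotypes: np.ndarray,
    expression: ExpressionParams,
    read_length: int,
    error_rate: float,
    seed: int | np.random.Generator,
    n_reads: int = 6000,
    tissues: tuple[str, ...] = ("normal", "tumor"),
    sample_ids: list[str] | None = None,
    abundances: dict | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Draw single-end reads from the transcripts active in each sample.

    Reads start uniformly over valid positions; per-base substitution
    errors are i.i.d. at ``error_rate``.  Read names carry truth tags
    ``sample|tissue|transcript|start|serial`` which downstream analysis
    code must never consult (tests only).  Returns ``(reads, truth)``
    where ``reads`` maps (sample, tissue) to a list of (name, sequence,
    quality) and ``truth`` tabulates molar abundances and read counts.
    """
    rng = seed if isinstance(seed, np.random.Generator) else child_rng(seed, "rnaseq")
    c_vec = np.asarray(genotypes)
    ids = sample_ids if sample_ids is not None else [f"S{i:04d}" for i in range(len(c_vec))]
    tx_names = sorted(locus_model.transcript_seqs)
    lens = {t: len(locus_model.transcript_seqs[t]) for t in tx_names}
    reads: dict[tuple[str, str], list[tuple[str, str, str]]] = {}
    truth_rows = []
    qual = "I" * read_length
    base_arr = np.frombuffer(b"ACGT", dtype=np.uint8)
    for sid, c in zip(ids, c_vec):
        for tissue in tissues:
            if abundances is not None and (sid, tissue) in abundances:
                ab = dict(abundances[(sid, tissue)])
                if c == 2 and ab.get("A3B", 0) > 0:
                    raise ValueError(f"{sid}: A3B abundance > 0 inconsistent with genotype c=2")
                if c == 2 and ab.get("A3A", 0) > 0:
                    raise ValueError(f"{sid}: A3A abundance > 0 inconsistent with genotype c=2")
                if c == 0 and ab.get("A3A_B", 0) > 0:
                    raise ValueError(f"{sid}: A3A_B abundance > 0 inconsistent with genotype c=0")
            else:
                ab = expression.sample_abundances(int(c), tissue)
            active = [t for t in tx_names if ab.get(t, 0.0) > 0]
            # reads per transcript scale with molar abundance x number of
            # start positions (effective length)
            w = np.array([ab[t] * max(lens[t] - read_length + 1, 1) for t in active], float)
            counts = rng.multinomial(n_reads, w / w.sum()) if active else np.array([], int)
            lib: list[tuple[str, str, str]] = []
            serial = 0
            for t, cnt in zip(active, counts):
                seq = locus_model.transcript_seqs[t]
                starts = rng.integers(0, lens[t] - read_length + 1, size=cnt)
                for st in starts:
                    r = seq[st : st + read_length]
                    if error_rate > 0:
                        errs = np.flatnonzero(rng.random(read_length) < error_rate)
                        if errs.size:
                            arr = np.frombuffer(r.encode(), dtype=np.uint8).copy()
                            for e in errs:
                                cur = arr[e]
                                repl = base_arr[rng.integers(0, 4)]
                                while repl == cur:
                                    repl = base_arr[rng.integers(0, 4)]
                                arr[e] = repl
                            r = arr.tobytes().decode()
                    lib.append((f"{sid}|{tissue}|{t}|{int(st)}|{serial}", r, qual))
                    serial += 1
                truth_rows.append(
                    {
                        "sample": sid,
                        "tissue": tissue,
                        "transcript": t,
                        "molar": ab[t],
                        "n_reads": int(cnt),
                    }
                )
            reads[(sid, tissue)] = lib
    truth = pd.DataFrame(truth_rows)
    return reads, truth


def build_context_genome(length: int, seed: int | np.random.Generator, name: str = "chrBG") -> dict:
    """Random background contig used to place simulated mutations in
    genuine sequence context."""
    rng = seed if isinstance(seed, np.random.Generator) else child_rng(seed, "context_genome")
    return {name: random_dna(rng, int(length))}


def _context_index(genome: dict[str, str]):
    """Index genome positions by pyrimidine-strand trinucleotide context.

    Returns ``pools[(five, ref, three)] = list of (chrom, pos0, strand)``
    and ``apobec_pools[(five, ref, three, yr)]`` splitting TCA/TCT
    contexts by the -2 base class (Y = pyrimidine, R = purine).
    """
    pools: dict[tuple, list] = {}
    apo: dict[tuple, list] = {}
    for chrom, seq in genome.items():
        s = seq.upper()
        for i in range(2, len(s) - 2):
            tri = s[i - 1 : i + 2]
            if any(b not in "ACGT" for b in tri):
                continue
            if tri[1] in "CT":
                key, strand, minus2 = (tri[0], tri[1], tri[2]), "+", s[i - 2]
            else:
                rc = revcomp(tri)
                key, strand, minus2 = (rc[0], rc[1], rc[2]), "-", _COMPL.get(s[i + 2], "N")
            pools.setdefault(key, []).append((chrom, i, strand))
            if key[1] == "C" and key[0] == "T" and key[2] in "AT" and minus2 in "ACGT":
                yr = "Y" if minus2 in "CT" else "R"
                apo.setdefault((*key, yr), []).append((chrom, i, strand))
    return pools, apo


def simulate_mutation_set(
    reference_signatures: pd.DataFrame,
    exposure_matrix_true: pd.DataFrame,
    context_genome: dict[str, str],
    yt_fraction_true: float,
    seed: int | np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-sample SNVs from a mixture of signatures.

    ``reference_signatures`` is 96 x K with columns summing to 1;
    ``exposure_matrix_true`` is K x S of expected mutation counts (its
    column sums set the per-sample burden).  Each mutation is placed at a
    genome position whose trinucleotide context matches its class, on
    either strand.  For APOBEC-context classes (C>T/C>G at TCW) the -2
    base encodes the deaminase preference: TCA-class mutations get a
    pyrimidine at -2 with probability ``yt_fraction_true`` and TCT-class
    mutations with the complementary probability, so an A3A-dominated
    catalog (high ``yt_fraction_true``) shows the YTCA enrichment that
    distinguishes A3A from A3B activity.

    Returns ``(mutations, truth_catalog)``: a MAF-like frame (1-based
    positions, genome-strand ref/alt/context) and the 96 x S truth count
    matrix.
    """
    from ..signatures.catalog import CLASS_LABELS, SUBSTITUTIONS

    P = np.asarray(reference_signatures, dtype=float)
    if P.shape[0] != 96:
        raise ValueError("reference signatures must have 96 rows")
    if np.any(P < 0):
        raise ValueError("reference signatures must be nonnegative")
    colsum = P.sum(axis=0)
    if not np.allclose(colsum[colsum > 0], 1.0, atol=1e-6):
        raise ValueError("reference signature columns must sum to 1")
    E = np.asarray(exposure_matrix_true, dtype=float)
    if np.any(E < 0):
        raise ValueError("exposures must be nonnegative")
    if isinstance(exposure_matrix_true, pd.DataFrame):
        sample_ids = list(exposure_matrix_true.columns)
    else:
        sample_ids = [f"S{i:04d}" for i in range(E.shape[1])]
    rng = seed if isinstance(seed, np.random.Generator) else child_rng(seed, "mutations")
    pools, apo = _context_index(context_genome)

    apobec_classes = {
        i
        for i, lab in enumerate(CLASS_LABELS)
        if lab[2:5] in ("C>T", "C>G") and lab[0] == "T" and lab[6] in "AT"
    }
    rows = []
    M_true = np.zeros((96, len(sample_ids)), dtype=int)
    for j, sid in enumerate(sample_ids):
        lam = P @ E[:, j]
        total = int(round(lam.sum()))
        if total == 0:
            continue
        probs = lam / lam.sum()
        counts = rng.multinomial(total, probs)
        M_true[:, j] = counts
        for ci in np.flatnonzero(counts):
            n = int(counts[ci])
            lab = CLASS_LABELS[ci]
            five, ref, alt, three = lab[0], lab[2], lab[4], lab[6]
            if ci in apobec_classes:
                p_y = yt_fraction_true if three == "A" else 1.0 - yt_fraction_true
                ny = rng.binomial(n, p_y)
                picks = []
                for yr, cnt in (("Y", ny), ("R", n - ny)):
                    if cnt == 0:
                        continue
                    pool = apo.get((five, ref, three, yr), [])
                    if not pool:
                        raise ValueError(
                            f"context genome lacks any {yr}-{five}{ref}{three} site "
                            f"for class {lab}"
                        )
                    picks += [pool[k] for k in rng.integers(0, len(pool), size=cnt)]
            else:
                pool = pools.get((five, ref, three), [])
                if not pool:
                    raise ValueError(f"context genome lacks trinucleotide {five}{ref}{three} "
                                     f"for class {lab}")
                picks = [pool[k] for k in rng.integers(0, len(pool), size=n)]
            for chrom, pos0, strand in picks:
                seq = context_genome[chrom]
                g_ref = seq[pos0]
                g_alt = alt if strand == "+" else _COMPL[alt]
                rows.append(
                    {
                        "sample": sid,
                        "chrom": chrom,
                        "pos": pos0 + 1,
                        "ref": g_ref,
                        "alt": g_alt,
                        "context": seq[pos0 - 1 : pos0 + 2],
                        "class_index": ci,
                    }
                )
    mutations = pd.DataFrame(
        rows, columns=["sample", "chrom", "pos", "ref", "alt", "context", "class_index"]
    )
    truth_catalog = pd.DataFrame(M_true, index=list(CLASS_LABELS), columns=sample_ids)
    return mutations, truth_catalog


def simulate_clinical_cohort(
    genotypes: np.ndarray,
    expression_groups: np.ndarray,
    survival_params: SurvivalParams,
    seed: int | np.random.Generator,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Exponential event times with group-specific hazards and
    independent censoring; returns time (months), event flag, group and
    basic covariates."""
    p = survival_params
    if any(h <= 0 for h in p.hazard_ratios.values()):
        raise ValueError("hazard ratios must be positive")
    if not 0.0 <= p.censoring_rate <= 1.0:
        raise ValueError("censoring_rate must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else child_rng(seed, "clinical")
    groups = np.asarray(expression_groups)
    n = len(groups)
    ids = sample_ids if sample_ids is not None else [f"S{i:04d}" for i in range(n)]
    haz = np.array([p.baseline_hazard * p.hazard_ratios[g] for g in groups])
    T = rng.exponential(1.0 / haz)
    if p.censoring_rate >= 1.0:
        time, event = rng.exponential(1.0 / p.baseline_hazard, size=n), np.zeros(n, int)
        time = np.minimum(time, p.max_followup)
    else:
        if p.censoring_rate > 0:
            hc = haz * p.censoring_rate / (1.0 - p.censoring_rate)
            C = rng.exponential(1.0 / hc)
        else:
            C = np.full(n, np.inf)
        C = np.minimum(C, p.max_followup)
        event = (T <= C).astype(int)
        time = np.minimum(T, C)
    return pd.DataFrame(
        {
            "sample": ids,
            "time": time,
            "event": event,
            "group": groups,
            "genotype": np.asarray(genotypes),
            "age_group": rng.integers(0, 2, size=n),
            "sex": (rng.random(n) < 0.9).astype(int),  # OSCC cohorts are male-dominated
        }
    )


@dataclass
class SimulatedCohort:
    """Everything one synthetic study produces, with ground truth."""

    config: SimConfig
    locus: LocusModel
    context_genome: dict
    sample_ids: list
    genotypes: np.ndarray
    depth: pd.DataFrame
    reads: dict
    expression_truth: pd.DataFrame
    mutations: pd.DataFrame
    truth_catalog: pd.DataFrame
    signatures_true: pd.DataFrame
    exposures_true: pd.DataFrame
    clinical: pd.DataFrame


def simulate_cohort(config: SimConfig | None = None) -> SimulatedCohort:
    """Run every generator stage under one root seed."""
    from ..signatures.reference import toy_reference_catalog

    cfg = config or SimConfig()
    locus = build_locus_model(cfg.locus, cfg.read_length)
    ids = [f"S{i:04d}" for i in range(cfg.n_samples)]
    genotypes = simulate_genotypes(cfg.n_samples, cfg.deletion_allele_freq, cfg.seed)
    depth = simulate_wes_depth(
        genotypes,
        cfg.mean_depth,
        cfg.depth_dispersion,
        cfg.seed,
        noise_floor=cfg.depth_noise_floor,
        sample_ids=ids,
    )
    reads, expr_truth = simulate_rnaseq_reads(
        locus,
        genotypes,
        cfg.expression,
        cfg.read_length,
        cfg.rnaseq_error_rate,
        cfg.seed,
        n_reads=cfg.n_reads_per_library,
        sample_ids=ids,
    )
    genome = build_context_genome(cfg.context_genome_len, cfg.seed)
    ref = toy_reference_catalog()
    sig_names = list(cfg.signature_weights)
    missing = [s for s in sig_names if s not in ref.columns]
    if missing:
        raise ValueError(f"unknown signature names in config: {missing}")
    P_true = ref[sig_names]
    w = np.array([cfg.signature_weights[s] for s in sig_names], float)
    w = w / w.sum()
    exp_rng = child_rng(cfg.seed, "exposures")
    per_sample_w = exp_rng.dirichlet(w * cfg.exposure_concentration, size=cfg.n_samples).T
    E_true = pd.DataFrame(
        per_sample_w * float(cfg.mutations_per_sample),
        index=sig_names,
        columns=ids,
    )
    mutations, truth_catalog = simulate_mutation_set(
        P_true, E_true, genome, cfg.yt_fraction_true, cfg.seed
    )
    # expression groups from true tumor gene-level A3A (A3A + A3A_B)
    tum = expr_truth[(expr_truth.tissue == "tumor") & expr_truth.transcript.isin(["A3A", "A3A_B"])]
    a3a = tum.groupby("sample").molar.sum().reindex(ids).fillna(0.0).to_numpy()
    groups = np.where(a3a > np.median(a3a), "high", "low")
    clinical = simulate_clinical_cohort(genotypes, groups, cfg.survival, cfg.seed, sample_ids=ids)
    return SimulatedCohort(
        config=cfg,
        locus=locus,
        context_genome=genome,
        sample_ids=ids,
        genotypes=genotypes,
        depth=depth,
        reads=reads,
        expression_truth=expr_truth,
        mutations=mutations,
        truth_catalog=truth_catalog,
        signatures_true=P_true.copy(),
        exposures_true=E_true,
        clinical=clinical,
    )
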