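"""The 96-class trinucleotide substitution catalog and tetranucleotide
(YTCA/RTCA) attribution of APOBEC-context mutations.

Single-nucleotide variants are keyed by the substituted pyrimidine (C or
T), its immediate 5' and 3' neighbours, and the alternate base; variants
reported on the purine strand are reverse-complemented first.  Class
ordering follows the COSMIC convention: substitution-major
(C>A, C>G, C>T, T>A, T>C, T>G), then 5' base, then 3' base, each in
A, C, G, T order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..sim.locus import revcomp

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_FLANKS = "ACGT"
N_CLASSES = 96

PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")

CLASS_LABELS = tuple(
    f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in _FLANKS for three in _FLANKS
)


def class_index(substitution: str, five: str, three: str) -> int:
    """Index 0-95 of a pyrimidine-strand substitution class."""
    return (
        SUBSTITUTIONS.index(substitution) * 16 + _FLANKS.index(five) * 4 + _FLANKS.index(three)
    )


def class_label(index: int) -> str:
    return CLASS_LABELS[index]


def pyrimidine_context(ref: str, alt: str, context: str) -> tuple[str, str, str]:
    """Normalise an SNV to the pyrimidine strand.

    ``context`` is the 5'->3' trinucleotide on the reference strand with
    the mutated base in the middle.  Returns ``(substitution, five,
    three)``; raises ``ValueError`` on inconsistent records (non-SNV
    alleles, context middle base differing from ``ref``).
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(ref) != 1 or len(alt) != 1 or ref == alt or {ref, alt} - set("ACGT"):
        raise ValueError(f"not a SNV: {ref}>{alt}")
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} inconsistent with ref {ref!r}")
    if ref in PURINES:
        context = revcomp(context)
        ref = context[1]
        alt = revcomp(alt)
    return f"{ref}>{alt}", context[0], context[2]


def _context_from_genome(genome: dict[str, str], chrom: str, pos1: int, flank: int = 1) -> str:
    seq = genome[chrom]
    i = pos1 - 1
    if i - flank < 0 or i + flank + 1 > len(seq):
        raise ValueError(f"position {chrom}:{pos1} too close to contig edge for context")
    return seq[i - flank : i + flank + 1].upper()


def build_catalog_96(
    mutations: pd.DataFrame,
    context_source: dict[str, str] | None = None,
    sample_col: str = "sample",
) -> tuple[pd.DataFrame, dict]:
    """Accumulate SNVs into a 96 x S count matrix.

    Parameters
    ----------
    mutations
        MAF-like frame with columns ``sample, chrom, pos, ref, alt`` and
        either a ``context`` column (5'->3' reference-strand trinucleotide)
        or positions resolvable in ``context_source``.
    context_source
        Mapping of contig name to sequence, used when ``context`` is
        absent; ``pos`` is interpreted 1-based.

    Returns
    -------
    catalog, report
        ``catalog`` is a 96 x S integer DataFrame indexed by class label;
        ``report`` counts accepted, skipped non-SNV and rejected records.
    """
    samples = list(pd.unique(mutations[sample_col]))
    M = np.zeros((N_CLASSES, len(samples)), dtype=int)
    col = {s: j for j, s in enumerate(samples)}
    report = {"accepted": 0, "skipped_non_snv": 0, "rejected": 0, "rejected_rows": []}
    has_ctx = "context" in mutations.columns
    for row in mutations.itertuples(index=False):
        ref, alt = str(row.ref), str(row.alt)
        if len(ref) != 1 or len(alt) != 1 or ref == "-" or alt == "-":
            report["skipped_non_snv"] += 1
            continue
        try:
            if has_ctx and isinstance(row.context, str) and row.context:
                ctx = row.context
            elif context_source is not None:
                ctx = _context_from_genome(context_source, str(row.chrom), int(row.pos))
            else:
                raise ValueError("no context column and no context_source")
            sub, five, three = pyrimidine_context(ref, alt, ctx)
        except ValueError as exc:
            report["rejected"] += 1
            report["rejected_rows"].append(str(exc))
            continue
        M[class_index(sub, five, three), col[getattr(row, sample_col)]] += 1
        report["accepted"] += 1
    catalog = pd.DataFrame(M, index=list(CLASS_LABELS), columns=samples)
    return catalog, report


# ---------------------------------------------------------------------------
# YTCA / RTCA tetranucleotide attribution


@dataclass
class TetranucCounts:
    """Per-sample counts of APOBEC-context mutated cytosines.

    Counts C>T and C>G mutations on the pyrimidine strand at TCA and TCW
    (W = A/T) motifs, split by the -2 base: Y (C/T, the A3A-like context)
    versus R (A/G, the A3B-like context).
    """

    counts: pd.DataFrame  # columns YTCA, RTCA, YTCW, RTCW per sample
    fractions: pd.DataFrame  # YTCA/YTCW and RTCA/RTCW per usable sample
    excluded_samples: list
    pooled_ytca_rtca: tuple[int, int]
    wilcoxon_stat: float
    wilcoxon_p: float


def tetranucleotide_attribution(
    mutations: pd.DataFrame,
    context_source: dict[str, str],
    sample_col: str = "sample",
) -> TetranucCounts:
    """Classify APOBEC-context mutations by their -2 base and compare
    the per-sample YTCA/YTCW and RTCA/RTCW fractions.

    A mutation enters the tally when, on the pyrimidine strand, it is a
    C>T or C>G change in a TCW motif (5' T, 3' A or T).  The -2 base is
    read from the genome on the same strand as the normalised context.
    The two per-sample fraction sets are compared with a two-sided
    Wilcoxon rank-sum test (exact when both groups have <= 12 usable
    samples and no ties; normal approximation with tie and continuity
    correction otherwise, as implemented in scipy's ``mannwhitneyu``).
    """
    from scipy import stats

    samples = list(pd.unique(mutations[sample_col]))
    tab = pd.DataFrame(0, index=samples, columns=["YTCA", "RTCA", "YTCW", "RTCW"])
    for row in mutations.itertuples(index=False):
        ref, alt = str(row.ref).upper(), str(row.alt).upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
            continue
        chrom, pos1 = str(row.chrom), int(row.pos)
        quad_fwd = _context_from_genome(context_source, chrom, pos1, flank=2)[:4]
        # pyrimidine-strand 4-mer (-2, -1, ref, +1)
        if ref in PYRIMIDINES:
            quad, ralt = quad_fwd, alt
        else:
            penta = _context_from_genome(context_source, chrom, pos1, flank=2)
            quad, ralt = revcomp(penta)[:4], revcomp(alt)
        if quad[2] != "C" or ralt not in ("T", "G"):
            continue
        if quad[1] != "T" or quad[3] not in "AT":
            continue
        minus2 = quad[0]
        yr = "Y" if minus2 in PYRIMIDINES else "R"
        tab.loc[getattr(row, sample_col), f"{yr}TCW"] += 1
        if quad[3] == "A":
            tab.loc[getattr(row, sample_col), f"{yr}TCA"] += 1

    usable = tab[(tab.YTCW > 0) & (tab.RTCW > 0)]
    excluded = [s for s in samples if s not in usable.index]
    fr = pd.DataFrame(
        {
            "ytca_over_ytcw": usable.YTCA / usable.YTCW,
            "rtca_over_rtcw": usable.RTCA / usable.RTCW,
        }
    )
    if len(usable) >= 1:
        x, y = fr.ytca_over_ytcw.to_numpy(), fr.rtca_over_rtcw.to_numpy()
        exact = len(x) <= 12 and len(y) <= 12 and len(np.unique(np.r_[x, y])) == len(x) + len(y)
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
        )
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        stat, p = float("nan"), float("nan")
    return TetranucCounts(
        counts=tab,
        fractions=fr,
        excluded_samples=excluded,
        pooled_ytca_rtca=(int(tab.YTCA.sum()), int(tab.RTCA.sum())),
        wilcoxon_stat=stat,
        wilcoxon_p=p,
    )
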