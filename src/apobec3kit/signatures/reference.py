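"""Reference signature catalogs.

A real analysis matches extracted signatures against the published
catalog of curated mutational signatures (supplied by the user as a
96-row TSV with one named column per signature).  For self-contained
testing this module also builds a small synthetic catalog of six
signature *analogs* — APOBEC-like (C>T and C>G at TpCpN, mirroring
signatures 2 and 13), two aging-like CpG deamination profiles
(signatures 1A/1B), a tobacco-like C>A profile (signature 4-like) and
one broad, flat profile (signature 5-like).  They are synthetic
constructions, not the published profiles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .catalog import CLASS_LABELS, N_CLASSES, class_index


def _profile(weights: dict[tuple[str, str, str], float], background: float = 0.0) -> np.ndarray:
    v = np.full(N_CLASSES, background, dtype=float)
    for (sub, five, three), w in weights.items():
        v[class_index(sub, five, three)] += w
    return v / v.sum()


def toy_reference_catalog() -> pd.DataFrame:
    """Six synthetic signature analogs as a 96 x 6 column-stochastic frame.

    The APOBEC-like, aging-like and tobacco-like profiles are mutually
    well-separated (pairwise cosine < 0.1), which the recovery tests
    rely on; the flat 5-like profile represents the clock-like
    background whose near-uniform shape is intrinsically the hardest to
    pin down from small catalogs.
    """
    apobec_ct = {("C>T", "T", t): w for t, w in zip("ACGT", (0.40, 0.10, 0.05, 0.40))}
    apobec_cg = {("C>G", "T", t): w for t, w in zip("ACGT", (0.40, 0.10, 0.05, 0.40))}
    aging_a = {("C>T", f, "G"): w for f, w in zip("ACGT", (0.30, 0.25, 0.25, 0.20))}
    aging_b = {("C>T", f, "G"): w for f, w in zip("ACGT", (0.15, 0.20, 0.20, 0.15))}
    aging_b.update({("C>T", f, "A"): 0.075 for f in "ACGT"})
    # tobacco-analog: C>A dominated with a 5' preference
    smoking = {
        ("C>A", f, t): wf * wt
        for f, wf in zip("ACGT", (0.20, 0.35, 0.15, 0.30))
        for t, wt in zip("ACGT", (0.30, 0.30, 0.15, 0.25))
    }
    # flat profile with a mild tilt toward T>C, as in clock-like damage
    flat = np.ones(N_CLASSES)
    for f in "ACGT":
        for t in "ACGT":
            flat[class_index("T>C", f, t)] = 2.0
    cols = {
        "SBS1Alike": _profile(aging_a, background=0.001),
        "SBS1Blike": _profile(aging_b, background=0.001),
        "SBS2like": _profile(apobec_ct, background=0.0005),
        "SBS4like": _profile(smoking, background=0.0005),
        "SBS5like": flat / flat.sum(),
        "SBS13like": _profile(apobec_cg, background=0.0005),
    }
    return pd.DataFrame(cols, index=list(CLASS_LABELS))


def load_reference_catalog(path) -> pd.DataFrame:
    """Load a 96-row reference signature TSV and renormalise columns."""
    ref = pd.read_csv(path, sep="\t", index_col=0)
    if ref.shape[0] != N_CLASSES:
        raise ValueError(f"reference catalog must have {N_CLASSES} rows, got {ref.shape[0]}")
    if (ref.to_numpy() < 0).any():
        raise ValueError("reference catalog contains negative entries")
    return ref / ref.sum(axis=0)
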