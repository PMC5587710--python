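"""Scaled-down synthetic model of the APOBEC3A-APOBEC3B locus.

The real germline polymorphism is a ~29.5-kb deletion running from the
3'UTR of *APOBEC3A* (A3A) to the eighth exon of *APOBEC3B* (A3B).  On the
deletion haplotype the A3A coding region is spliced onto the A3B 3'UTR,
producing the fusion transcript *A3A_B* whose coding sequence is identical
to A3A and whose 3'UTR is identical to A3B.  Everything downstream
(junction databases, read assignment, genotype-aware quantification)
depends only on that sharing structure, not on hg19 coordinates, so this
module builds a parameterised miniature locus (kilobase scale) with the
same topology:

* a non-deleted haplotype contig carrying A3A (coding exon + 3'UTR exon)
  and A3B (two coding exons + 3'UTR exon),
* a deleted haplotype contig equal to the non-deleted one with the
  deletion interval excised, carrying the fusion transcript A3A_B,
* a separate "housekeeping" contig, identical on both haplotypes, with
  two spike-in transcripts used as always-active quantification anchors.

All coordinates are 0-based half-open on the forward strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = np.array(list("ACGT"))

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC ACGTN)."""
    return seq.translate(COMPLEMENT)[::-1]


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _mutate_to_similarity(rng: np.random.Generator, seq: str, identity: float) -> str:
    """Return a copy of ``seq`` whose per-base identity to it is ``identity``
    in expectation (substitutions only, drawn uniformly from the 3 other bases)."""
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) > identity
    for i in np.flatnonzero(hit):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


@dataclass(frozen=True)
class LocusParams:
    """Segment lengths (bp) of the miniature locus.

    Defaults give a ~3-kb deletion with exons of 200-400 bp, large enough
    for 151-bp reads and 150-bp junction flanks on every exon.
    """

    a3a_coding_len: int = 360
    a3a_utr_len: int = 260
    a3b_coding_exon_lens: tuple[int, ...] = (300, 300)
    a3b_utr_len: int = 260
    intron_len: int = 220
    intergenic_len: int = 400
    flank_len: int = 420
    breakpoint_margin: int = 110  # intron bases kept on each side of the deletion
    coding_identity: float = 0.92  # A3B coding similarity to A3A coding
    hk_exon_lens: tuple[tuple[int, ...], ...] = ((320, 280), (520,))
    seed: int = 2022


@dataclass
class LocusModel:
    """Haplotype contigs, exon tables and transcript sequences."""

    contigs: dict[str, dict[str, str]]  # haplotype -> {contig name -> sequence}
    deletion_interval: tuple[int, int]  # on the non-deleted main contig
    exons: pd.DataFrame  # transcript_id, haplotype, contig, exon_index, start, end, segment
    transcript_seqs: dict[str, str]
    shared_segments: dict[str, tuple[str, str]] = field(default_factory=dict)
    params: LocusParams = field(default_factory=LocusParams)

    MAIN_CONTIG = "chrA3"
    HK_CONTIG = "chrHK"

    def transcript_length(self, name: str) -> int:
        return len(self.transcript_seqs[name])

    def junctions(self) -> pd.DataFrame:
        """Per-transcript splice junctions as transcript-space offsets.

        Returns a frame with transcript_id, junction_index and ``tx_pos``,
        the transcript coordinate of the first base of the downstream exon.
        """
        rows = []
        for tx, sub in self.exons.groupby("transcript_id", sort=False):
            sub = sub.sort_values("exon_index")
            lens = (sub["end"] - sub["start"]).to_numpy()
            pos = 0
            for j in range(len(lens) - 1):
                pos += int(lens[j])
                rows.append({"transcript_id": tx, "junction_index": j, "tx_pos": pos})
        return pd.DataFrame(rows, columns=["transcript_id", "junction_index", "tx_pos"])

    def fusion_junction_pos(self) -> int:
        """Transcript coordinate of the A3A_B coding->3'UTR fusion point."""
        jc = self.junctions()
        row = jc[jc.transcript_id == "A3A_B"]
        if row.empty:
            raise ValueError("locus model has no A3A_B fusion transcript")
        return int(row.tx_pos.iloc[0])


def build_locus_model(params: LocusParams | None = None, read_length: int = 151) -> LocusModel:
    """Construct the two haplotype contigs and their transcript models.

    Raises ``ValueError`` when any exon is shorter than ``read_length``:
    junction flanks of ``read_length - 1`` bases could then not be taken
    from a single exon pair and reads could span two junctions at once,
    which the miniature locus deliberately avoids.
    """
    p = params or LocusParams()
    all_exons = [p.a3a_coding_len, p.a3a_utr_len, *p.a3b_coding_exon_lens, p.a3b_utr_len]
    all_exons += [l for ex in p.hk_exon_lens for l in ex]
    if min(all_exons) < read_length:
        raise ValueError(
            f"exon of {min(all_exons)} bp is shorter than read_length={read_length}; "
            "junction flanks would be impossible"
        )
    rng = np.random.default_rng(p.seed)

    a3a_coding = random_dna(rng, p.a3a_coding_len)
    a3a_utr = random_dna(rng, p.a3a_utr_len)
    n_b_coding = sum(p.a3b_coding_exon_lens)
    shared = _mutate_to_similarity(rng, a3a_coding, p.coding_identity)
    a3b_coding = (shared + random_dna(rng, n_b_coding - len(shared)))[:n_b_coding]
    a3b_utr = random_dna(rng, p.a3b_utr_len)

    # assemble the non-deleted contig left to right, recording exon coords
    pieces: list[str] = []
    cursor = 0
    exon_rows: list[dict] = []

    def emit(seq: str, tx: str | None = None, segment: str | None = None):
        nonlocal cursor
        pieces.append(seq)
        if tx is not None:
            exon_rows.append(
                {"transcript_id": tx, "start": cursor, "end": cursor + len(seq), "segment": segment}
            )
        cursor += len(seq)

    emit(random_dna(rng, p.flank_len))
    emit(a3a_coding, "A3A", "coding")
    a3a_coding_end = cursor
    emit(random_dna(rng, p.intron_len))
    emit(a3a_utr, "A3A", "utr3")
    emit(random_dna(rng, p.intergenic_len))
    b_exons = []
    for i, (seq_len, off) in enumerate(
        zip(p.a3b_coding_exon_lens, np.cumsum((0,) + p.a3b_coding_exon_lens[:-1]))
    ):
        emit(a3b_coding[off : off + seq_len], "A3B", "coding")
        b_exons.append(exon_rows[-1])
        emit(random_dna(rng, p.intron_len))
    emit(a3b_utr, "A3B", "utr3")
    a3b_utr_start = exon_rows[-1]["start"]
    emit(random_dna(rng, p.flank_len))

    contig_nd = "".join(pieces)
    del_start = a3a_coding_end + p.breakpoint_margin
    del_end = a3b_utr_start - p.breakpoint_margin
    deletion = (del_start, del_end)
    contig_del = contig_nd[:del_start] + contig_nd[del_end:]
    del_len = del_end - del_start

    for i, row in enumerate(exon_rows):
        row["exon_index"] = sum(r["transcript_id"] == row["transcript_id"] for r in exon_rows[:i])
        row["haplotype"] = "nondeleted"
        row["contig"] = LocusModel.MAIN_CONTIG

    # fusion transcript lives on the deleted haplotype: A3A coding exon
    # (coordinates unchanged) spliced to the shifted A3B 3'UTR exon
    fusion_rows = [
        {
            "transcript_id": "A3A_B",
            "start": a3a_coding_end - p.a3a_coding_len,
            "end": a3a_coding_end,
            "segment": "coding",
            "exon_index": 0,
            "haplotype": "deleted",
            "contig": LocusModel.MAIN_CONTIG,
        },
        {
            "transcript_id": "A3A_B",
            "start": a3b_utr_start - del_len,
            "end": a3b_utr_start - del_len + p.a3b_utr_len,
            "segment": "utr3",
            "exon_index": 1,
            "haplotype": "deleted",
            "contig": LocusModel.MAIN_CONTIG,
        },
    ]

    hk_pieces: list[str] = []
    hk_cursor = 0
    hk_rows: list[dict] = []
    hk_pieces.append(random_dna(rng, 200))
    hk_cursor += 200
    for g, ex_lens in enumerate(p.hk_exon_lens):
        tx = f"HK{g + 1}"
        for j, l in enumerate(ex_lens):
            seq = random_dna(rng, l)
            hk_rows.append(
                {
                    "transcript_id": tx,
                    "start": hk_cursor,
                    "end": hk_cursor + l,
                    "segment": "coding",
                    "exon_index": j,
                    "haplotype": "both",
                    "contig": LocusModel.HK_CONTIG,
                }
            )
            hk_pieces.append(seq)
            hk_cursor += l
            if j < len(ex_lens) - 1:
                hk_pieces.append(random_dna(rng, p.intron_len))
                hk_cursor += p.intron_len
        hk_pieces.append(random_dna(rng, 200))
        hk_cursor += 200
    contig_hk = "".join(hk_pieces)

    exons = pd.DataFrame(exon_rows + fusion_rows + hk_rows)[
        ["transcript_id", "haplotype", "contig", "exon_index", "start", "end", "segment"]
    ].sort_values(["transcript_id", "exon_index"], ignore_index=True)

    contigs = {
        "nondeleted": {LocusModel.MAIN_CONTIG: contig_nd, LocusModel.HK_CONTIG: contig_hk},
        "deleted": {LocusModel.MAIN_CONTIG: contig_del, LocusModel.HK_CONTIG: contig_hk},
    }

    tx_seqs: dict[str, str] = {}
    for tx, sub in exons.groupby("transcript_id", sort=False):
        hap = sub.haplotype.iloc[0]
        hap_key = "nondeleted" if hap in ("nondeleted", "both") else "deleted"
        contig = contigs[hap_key][sub.contig.iloc[0]]
        tx_seqs[tx] = "".join(
            contig[int(r.start) : int(r.end)] for r in sub.sort_values("exon_index").itertuples()
        )

    model = LocusModel(
        contigs=contigs,
        deletion_interval=deletion,
        exons=exons,
        transcript_seqs=tx_seqs,
        shared_segments={
            "coding": ("A3A", "A3A_B"),  # identical coding sequence
            "utr3": ("A3B", "A3A_B"),  # identical 3'UTR sequence
        },
        params=p,
    )
    # construction invariants
    assert tx_seqs["A3A_B"] == a3a_coding + a3b_utr
    assert len(contig_del) == len(contig_nd) - del_len
    return model
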