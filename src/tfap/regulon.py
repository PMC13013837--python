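"""Regulon prediction: promoter extraction and PWM motif scanning.

A TF's regulon is the set of genes whose promoter window contains at
least one binding-motif hit above threshold. Scanning is log2-odds
scoring of a position probability matrix against both strands at
every offset; coordinates are BED-style 0-based half-open throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from pyfaidx import Fasta

from tfap._errors import ConfigError

BASES = "ACGT"
UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)
_CODE = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Motif:
    """Position probability matrix for one TF (rows A, C, G, T)."""

    tf_id: str
    matrix: np.ndarray  # (4, L) column-stochastic probabilities
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape[0] != 4 or m.shape[1] < 4:
            raise ConfigError(
                f"motif {self.tf_id!r}: matrix must be 4 x L with L >= 4, "
                f"got {m.shape}"
            )
        if not np.allclose(m.sum(axis=0), 1.0, atol=1e-9):
            raise ConfigError(
                f"motif {self.tf_id!r}: columns must sum to 1 after "
                "regularization"
            )
        object.__setattr__(self, "matrix", m)

    @classmethod
    def from_counts(
        cls, tf_id: str, counts: np.ndarray, pseudocount: float = 0.01
    ) -> "Motif":
        """Regularize a count (or probability) matrix into a PPM.

        Adds ``pseudocount`` to every cell, then renormalizes columns.
        """
        c = np.asarray(counts, dtype=float) + pseudocount
        return cls(tf_id, c / c.sum(axis=0, keepdims=True), pseudocount)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))

    def log_odds(
        self, background: Sequence[float] = UNIFORM_BACKGROUND
    ) -> np.ndarray:
        bg = np.asarray(background, dtype=float).reshape(4, 1)
        if not np.isclose(bg.sum(), 1.0):
            raise ConfigError("background frequencies must sum to 1")
        return np.log2(self.matrix) - np.log2(bg)

    def max_score(
        self, background: Sequence[float] = UNIFORM_BACKGROUND
    ) -> float:
        return float(self.log_odds(background).max(axis=0).sum())


class Hit(NamedTuple):
    """One motif match: window [offset, offset+L) on the given sequence."""

    offset: int
    strand: str
    score: float


@dataclass(frozen=True)
class PromoterRecord:
    """Gene-oriented promoter window (5'->3' relative to the gene)."""

    gene: str
    sequence: str
    contig: str
    start: int  # genomic, 0-based half-open
    end: int
    strand: str


def _encode(sequence: str) -> np.ndarray:
    return np.array([_CODE.get(b, 4) for b in sequence.upper()], dtype=np.intp)


def pwm_scan(
    sequence: str,
    motif: Motif,
    background: Sequence[float] = UNIFORM_BACKGROUND,
    min_score_bits: float = 0.0,
) -> list[Hit]:
    """Score a motif at every offset on both strands of ``sequence``.

    Returns hits with log2-odds score >= ``min_score_bits``; windows
    containing N score -inf and never match. A '-' hit at offset i
    means the motif matches the reverse complement of window
    [i, i+L).
    """
    L = motif.length
    codes = _encode(sequence)
    if codes.size < L:
        return []
    lo = motif.log_odds(background)
    # row 4 sinks N positions to -inf
    lookup = np.vstack([lo, np.full((1, L), -np.inf)])
    rc = lo[::-1, ::-1]
    lookup_rc = np.vstack([rc, np.full((1, L), -np.inf)])
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    cols = np.arange(L)
    fwd = lookup[windows, cols].sum(axis=1)
    rev = lookup_rc[windows, cols].sum(axis=1)
    hits = [
        Hit(int(i), "+", float(s))
        for i, s in enumerate(fwd)
        if s >= min_score_bits
    ]
    hits += [
        Hit(int(i), "-", float(s))
        for i, s in enumerate(rev)
        if s >= min_score_bits
    ]
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def extract_promoters(
    tss_bed,
    genome_fasta,
    upstream_bp: int = 1000,
    downstream_bp: int = 200,
) -> dict[str, PromoterRecord]:
    """Promoter windows around TSSs from a BED6 file and a genome FASTA.

    Plus strand: genomic [tss - upstream, tss + downstream). Minus
    strand: the mirrored window [tss - downstream + 1, tss + upstream
    + 1), reverse-complemented so the returned sequence reads
    5'->3' relative to the gene. Windows are clipped at contig bounds
    with a warning.
    """
    bed = pd.read_csv(
        tss_bed,
        sep="\t",
        header=None,
        names=["contig", "start", "end", "name", "score", "strand"],
    )
    genome = Fasta(str(genome_fasta))
    out: dict[str, PromoterRecord] = {}
    for row in bed.itertuples():
        if row.contig not in genome:
            raise KeyError(
                f"contig {row.contig!r} for gene {row.name!r} absent from "
                "genome FASTA"
            )
        contig_len = len(genome[row.contig])
        tss = int(row.start)
        if row.strand == "+":
            start, end = tss - upstream_bp, tss + downstream_bp
        elif row.strand == "-":
            start, end = tss - downstream_bp + 1, tss + upstream_bp + 1
        else:
            raise ValueError(
                f"gene {row.name!r}: strand must be '+' or '-', "
                f"got {row.strand!r}"
            )
        clipped_start, clipped_end = max(0, start), min(contig_len, end)
        if (clipped_start, clipped_end) != (start, end):
            warnings.warn(
                f"promoter window of {row.name!r} clipped to contig bounds "
                f"[{clipped_start}, {clipped_end})",
                stacklevel=2,
            )
        seq = str(genome[row.contig][clipped_start:clipped_end]).upper()
        if row.strand == "-":
            seq = reverse_complement(seq)
        out[str(row.name)] = PromoterRecord(
            gene=str(row.name),
            sequence=seq,
            contig=str(row.contig),
            start=clipped_start,
            end=clipped_end,
            strand=str(row.strand),
        )
    return out


@dataclass
class RegulonMap:
    """TF -> predicted target genes with best log2-odds score per gene."""

    scores: dict[str, dict[str, float]]
    empty_tfs: set[str] = field(default_factory=set)

    def targets(self, tf_id: str) -> set[str]:
        return set(self.scores.get(tf_id, {}))

    @property
    def tf_ids(self) -> list[str]:
        return sorted(set(self.scores) | self.empty_tfs)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"tf_id": tf, "gene": gene, "best_score_bits": score}
            for tf in sorted(self.scores)
            for gene, score in sorted(self.scores[tf].items())
        ]
        return pd.DataFrame(rows, columns=["tf_id", "gene", "best_score_bits"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RegulonMap":
        scores: dict[str, dict[str, float]] = {}
        for row in frame.itertuples():
            scores.setdefault(str(row.tf_id), {})[str(row.gene)] = float(
                row.best_score_bits
            )
        return cls(scores)


def resolve_threshold(
    motif: Motif,
    threshold_policy: tuple[str, float],
    background: Sequence[float] = UNIFORM_BACKGROUND,
) -> float:
    """Turn a threshold policy into bits for one motif.

    ``('relative', f)`` means f x the motif's maximum achievable
    score; ``('bits', x)`` is an absolute cutoff.
    """
    kind, value = threshold_policy
    if kind == "relative":
        if not 0 < value <= 1:
            raise ConfigError(f"relative threshold must be in (0, 1], got {value}")
        return value * motif.max_score(background)
    if kind == "bits":
        return float(value)
    raise ConfigError(f"unknown threshold policy {kind!r}")


def build_regulon_map(
    promoters: Mapping[str, PromoterRecord] | Mapping[str, str],
    motifs: Sequence[Motif],
    threshold_policy: tuple[str, float] = ("relative", 0.8),
    background: Sequence[float] = UNIFORM_BACKGROUND,
) -> RegulonMap:
    """Scan every promoter with every motif and collect targets.

    A gene joins a TF's regulon iff its promoter has >= 1 hit at or
    above the resolved threshold; the best hit score is retained.
    Hits on either strand count once (membership is a set). TFs with
    no targets are flagged, not dropped.
    """
    if not motifs:
        raise ConfigError("need at least one motif")
    if not promoters:
        raise ConfigError("need at least one promoter")
    seqs = {
        gene: (rec.sequence if isinstance(rec, PromoterRecord) else rec)
        for gene, rec in promoters.items()
    }
    scores: dict[str, dict[str, float]] = {}
    empty: set[str] = set()
    for motif in motifs:
        threshold = resolve_threshold(motif, threshold_policy, background)
        per_gene: dict[str, float] = {}
        for gene, seq in seqs.items():
            hits = pwm_scan(seq, motif, background, threshold)
            if hits:
                per_gene[gene] = max(h.score for h in hits)
        if per_gene:
            scores[motif.tf_id] = per_gene
        else:
            empty.add(motif.tf_id)
            warnings.warn(
                f"motif {motif.tf_id!r}: no promoter passes the threshold; "
                "regulon empty",
                stacklevel=2,
            )
    return RegulonMap(scores, empty)


def read_jaspar(path, pseudocount: float = 0.01) -> list[Motif]:
    """Read JASPAR-format PFMs into regularized probability motifs."""
    with open(path) as handle:
        records = bio_motifs.parse(handle, "jaspar")
        out = []
        for rec in records:
            counts = np.array(
                [rec.counts[b] for b in BASES], dtype=float
            )
            name = rec.matrix_id or rec.name
            out.append(Motif.from_counts(str(name), counts, pseudocount))
    return out


def write_jaspar(motif_list: Sequence[Motif], path) -> None:
    """Write motifs as JASPAR PFM text (probabilities as matrix cells)."""
    with open(path, "w") as handle:
        for m in motif_list:
            handle.write(f">{m.tf_id} {m.tf_id}\n")
            for i, base in enumerate(BASES):
                cells = " ".join(f"{v:.6f}" for v in m.matrix[i])
                handle.write(f"{base} [ {cells} ]\n")


def write_regulons_tsv(regmap: RegulonMap, path) -> None:
    regmap.to_frame().to_csv(path, sep="\t", index=False)


def write_regulons_gmt(regmap: RegulonMap, path) -> None:
    """Gene-set (GMT) export: one tab-separated line per TF."""
    with open(path, "w") as handle:
        for tf in sorted(regmap.scores):
            genes = "\t".join(sorted(regmap.scores[tf]))
            handle.write(f"{tf}\tpredicted_regulon\t{genes}\n")
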