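"""Windowed conservation profiles and proline-framed subdomain extraction.

Intrinsically disordered regions resist structure-based domain mapping, so
functional subdomains are inferred from evolution instead: short windows of
high pairwise identity/similarity across an ortholog alignment, combined
with per-codon Bayes factors for purifying selection (dN < dS) produced by
an external random-effects likelihood test.  Candidate subdomains are the
maximal proline-free runs of the reference sequence — prolines provide the
flexible joints between putative interaction modules — annotated with the
mean of each profile and flagged when the mean Bayes factor exceeds the
agreement cutoff (default > 40) or the mean identity passes a user-chosen
threshold.

Coordinates are 1-based inclusive on the ungapped reference sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment, substitution_matrices


@dataclass
class ProteinMSA:
    """Aligned protein sequences with a designated reference row."""

    ids: list[str]
    rows: list[str]
    reference_id: str

    def __post_init__(self) -> None:
        lens = {len(r) for r in self.rows}
        if len(lens) != 1:
            raise ValueError("alignment rows differ in length")
        if self.reference_id not in self.ids:
            raise ValueError(f"reference {self.reference_id!r} not in alignment")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def reference_row(self) -> str:
        return self.rows[self.ids.index(self.reference_id)]

    @property
    def reference_sequence(self) -> str:
        return self.reference_row.replace("-", "")

    def reference_columns(self) -> np.ndarray:
        """Alignment column index (0-based) of each ungapped reference residue."""
        return np.flatnonzero(np.frombuffer(self.reference_row.encode(), dtype="S1") != b"-")


def read_msa(path: str, reference_id: str) -> ProteinMSA:
    aln = AlignIO.read(path, "fasta")
    return ProteinMSA(ids=[r.id for r in aln], rows=[str(r.seq).upper() for r in aln],
                      reference_id=reference_id)


def write_msa(msa: ProteinMSA, path: str) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    aln = MultipleSeqAlignment(
        [SeqRecord(Seq(row), id=sid, description="") for sid, row in zip(msa.ids, msa.rows)]
    )
    AlignIO.write(aln, path, "fasta")


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average, truncated at the ends, NaN-renormalized."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(values):
        raise ValueError("window exceeds profile length")
    n = len(values)
    left = (window - 1) // 2
    right = window // 2
    out = np.full(n, np.nan)
    for i in range(n):
        seg = values[max(0, i - left): min(n, i + right + 1)]
        seg = seg[~np.isnan(seg)]
        if len(seg):
            out[i] = seg.mean()
    return out


def _column_matrix(msa: ProteinMSA) -> np.ndarray:
    return np.array([list(r) for r in msa.rows])


def windowed_identity(msa: ProteinMSA, window: int = 4) -> pd.Series:
    """Per-reference-position mean pairwise identity, window-averaged.

    Per alignment column, identity is the fraction of sequence pairs with
    identical residues among pairs where neither is a gap; the profile is
    smoothed with a centered window and reported at ungapped reference
    coordinates (1-based).
    """
    cols = _column_matrix(msa)
    n_seq, n_col = cols.shape
    ident = np.full(n_col, np.nan)
    for j in range(n_col):
        col = cols[:, j]
        res = col[col != "-"]
        if len(res) < 2:
            continue
        # identical pairs = sum over residues of C(count, 2)
        _, counts = np.unique(res, return_counts=True)
        same = (counts * (counts - 1) // 2).sum()
        total = len(res) * (len(res) - 1) // 2
        ident[j] = same / total
    smooth = _moving_average(ident, window)
    ref_cols = msa.reference_columns()
    return pd.Series(smooth[ref_cols],
                     index=pd.RangeIndex(1, len(ref_cols) + 1, name="position"),
                     name="identity")


def windowed_similarity(msa: ProteinMSA, window: int = 20,
                        matrix_name: str = "BLOSUM62") -> pd.Series:
    """Mean pairwise substitution score per column, rescaled to [0, 1].

    Scores use a substitution matrix (default BLOSUM62); each column's mean
    pair score is mapped to [0, 1] by the matrix's global min/max, then
    window-averaged and reported at reference coordinates.
    """
    mat = substitution_matrices.load(matrix_name)
    smin, smax = float(np.min(mat)), float(np.max(mat))
    cols = _column_matrix(msa)
    n_seq, n_col = cols.shape
    sim = np.full(n_col, np.nan)
    for j in range(n_col):
        res = [r for r in cols[:, j] if r != "-"]
        if len(res) < 2:
            continue
        scores = []
        for a in range(len(res)):
            for b in range(a + 1, len(res)):
                try:
                    scores.append(float(mat[res[a], res[b]]))
                except (KeyError, IndexError) as exc:
                    raise ValueError(f"residue pair {res[a]}/{res[b]} absent from "
                                     f"{matrix_name}") from exc
        sim[j] = (np.mean(scores) - smin) / (smax - smin)
    smooth = _moving_average(sim, window)
    ref_cols = msa.reference_columns()
    return pd.Series(smooth[ref_cols],
                     index=pd.RangeIndex(1, len(ref_cols) + 1, name="position"),
                     name="similarity")


def windowed_bayes(bf: pd.Series, window: int = 4, length: int | None = None) -> pd.Series:
    """Sliding-window mean of per-codon Bayes factors.

    ``bf`` is indexed by 1-based codon position; codons absent from the
    table are treated as missing and the window mean is renormalized over
    the codons present.  ``length`` extends the profile to the full
    reference length (positions past the table are NaN-filled before
    smoothing).
    """
    if len(bf) == 0:
        raise ValueError("empty Bayes-factor table")
    n = int(length if length is not None else bf.index.max())
    values = np.full(n, np.nan)
    idx = bf.index.to_numpy(dtype=int)
    if (idx < 1).any() or (idx > n).any():
        raise ValueError("codon index outside reference range")
    values[idx - 1] = bf.to_numpy(dtype=float)
    if np.isnan(values).all():
        raise ValueError("all codons missing")
    smooth = _moving_average(values, window)
    return pd.Series(smooth, index=pd.RangeIndex(1, n + 1, name="position"), name="bf")


@dataclass
class SubdomainSegment:
    """A proline-framed interval of the reference protein."""

    start: int  # 1-based inclusive
    end: int
    mean_identity: float = np.nan
    mean_similarity: float = np.nan
    mean_bf: float = np.nan
    selected: bool = False
    conserved: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end or self.start < 1:
            raise ValueError("invalid segment interval")


def proline_segments(reference_sequence: str) -> list[SubdomainSegment]:
    """Maximal proline-free runs of the reference, 1-based inclusive."""
    seq = reference_sequence.upper()
    if not seq:
        raise ValueError("empty reference sequence")
    segments = []
    start = None
    for i, aa in enumerate(seq, start=1):
        if aa == "P":
            if start is not None:
                segments.append(SubdomainSegment(start=start, end=i - 1))
                start = None
        elif start is None:
            start = i
    if start is not None:
        segments.append(SubdomainSegment(start=start, end=len(seq)))
    return segments


def annotate_segments(segments: list[SubdomainSegment],
                      identity_profile: pd.Series | None = None,
                      similarity_profile: pd.Series | None = None,
                      bf_profile: pd.Series | None = None,
                      bf_cutoff: float = 40.0,
                      identity_threshold: float = 0.8) -> list[SubdomainSegment]:
    """Attach per-segment profile means and selection/conservation flags."""
    def seg_mean(profile: pd.Series | None, seg: SubdomainSegment) -> float:
        if profile is None:
            return float("nan")
        if seg.end > profile.index.max():
            raise ValueError(f"segment [{seg.start},{seg.end}] outside profile range")
        vals = profile.loc[seg.start: seg.end].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        return float(vals.mean()) if len(vals) else float("nan")

    out = []
    for seg in segments:
        mi = seg_mean(identity_profile, seg)
        ms = seg_mean(similarity_profile, seg)
        mb = seg_mean(bf_profile, seg)
        out.append(SubdomainSegment(
            start=seg.start, end=seg.end,
            mean_identity=mi, mean_similarity=ms, mean_bf=mb,
            selected=bool(np.isfinite(mb) and mb > bf_cutoff),
            conserved=bool(np.isfinite(mi) and mi >= identity_threshold),
        ))
    return out


def read_bf_table(path: str) -> pd.Series:
    """Two-column TSV (codon index 1-based, Bayes factor) to a Series."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return pd.Series(df.iloc[:, 1].to_numpy(dtype=float),
                     index=df.iloc[:, 0].to_numpy(dtype=int), name="bf")


def scan(msa: ProteinMSA, bf: pd.Series, window_identity: int = 4,
         window_similarity: int = 20, window_bf: int = 4,
         bf_cutoff: float = 40.0, identity_threshold: float = 0.8):
    """Full conservation scan: profiles plus annotated proline segments."""
    ident = windowed_identity(msa, window=window_identity)
    sim = windowed_similarity(msa, window=window_similarity)
    bfp = windowed_bayes(bf, window=window_bf, length=len(msa.reference_sequence))
    segs = proline_segments(msa.reference_sequence)
    segs = annotate_segments(segs, ident, sim, bfp, bf_cutoff=bf_cutoff,
                             identity_threshold=identity_threshold)
    profiles = pd.DataFrame({"identity": ident, "similarity": sim, "bf": bfp})
    return profiles, segs
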