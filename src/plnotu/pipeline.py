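"""Simplified reads-to-counts pipeline for amplicon metabarcoding.

Four self-contained steps: (i) quality/length filtering of reads,
(ii) greedy centroid OTU clustering of dereplicated sequences at a fixed
identity (97% by default — deliberately high so that low-divergence
haplotypes of a marker like ITS-2 stay separate), (iii) mapping reads back
to the representative set, and (iv) counting *unambiguous* best matches per
sample: a read whose top two identities tie is left unassigned.

Identity between two sequences is defined on a global alignment with free
end gaps as matching columns divided by alignment length (internal gaps
counted, terminal overhangs not).
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align, SeqIO

from .counts import CountTable

__all__ = [
    "SequenceRecord",
    "OtuCatalog",
    "read_sequences",
    "filter_reads",
    "dereplicate",
    "pairwise_identity",
    "cluster_otus",
    "map_reads",
    "counts_from_reads",
]

_VALID = set("ACGTN")


@dataclass
class SequenceRecord:
    """One read: id, originating sample, bases, optional per-base qualities."""

    id: str
    sample_id: str
    bases: str
    quals: list[int] | None = None

    def __post_init__(self) -> None:
        self.bases = self.bases.upper()
        if set(self.bases) - _VALID:
            bad = sorted(set(self.bases) - _VALID)
            raise ValueError(f"read {self.id!r}: invalid bases {bad}")
        if self.quals is not None and len(self.quals) != len(self.bases):
            raise ValueError(f"read {self.id!r}: quality/sequence length mismatch")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class OtuCatalog:
    """Representative sequences plus per-(OTU, sample) unambiguous counts."""

    representatives: dict[str, str] = field(default_factory=dict)
    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    unassigned: dict[str, int] = field(default_factory=dict)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.representatives)

    def count_table(self, factors: pd.DataFrame | None = None,
                    sample_ids=None) -> CountTable:
        samples = list(sample_ids) if sample_ids is not None else sorted(
            {s for (_, s) in self.counts} | set(self.unassigned)
        )
        mat = pd.DataFrame(
            0, index=pd.Index(samples), columns=self.otu_ids, dtype=np.int64
        )
        for (o, s), n in self.counts.items():
            mat.loc[s, o] = n
        fac = factors.loc[samples] if factors is not None else None
        return CountTable(mat, fac)


# ---------------------------------------------------------------------------
# IO and filtering
# ---------------------------------------------------------------------------

def _open_maybe_gz(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_sequences(path, sample_id: str, format: str | None = None) -> list[SequenceRecord]:
    """Read FASTA or FASTQ (optionally gzipped) into records for one sample."""
    p = Path(path)
    if format is None:
        stem = p.name[:-3] if p.suffix == ".gz" else p.name
        format = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    out = []
    with _open_maybe_gz(p) as fh:
        for rec in SeqIO.parse(fh, format):
            quals = rec.letter_annotations.get("phred_quality")
            out.append(
                SequenceRecord(rec.id, sample_id, str(rec.seq), list(quals) if quals else None)
            )
    return out


def filter_reads(
    records,
    min_len: int = 290,
    min_q: int = 20,
    max_frac_below: float = 0.2,
) -> list[SequenceRecord]:
    """Length and quality filtering.

    Keeps reads of length >= ``min_len`` whose fraction of bases below
    quality ``min_q`` is <= ``max_frac_below``; reads without qualities pass
    the quality check vacuously.
    """
    kept = []
    for r in records:
        if len(r) < min_len:
            continue
        if r.quals is not None:
            frac = sum(q < min_q for q in r.quals) / len(r.quals)
            if frac > max_frac_below:
                continue
        kept.append(r)
    return kept


def dereplicate(records) -> list[tuple[str, int]]:
    """Unique sequences with abundances, sorted by abundance descending,
    ties broken lexicographically (makes downstream clustering deterministic)."""
    tally = Counter(r.bases for r in records)
    return sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))


# ---------------------------------------------------------------------------
# Alignment identity
# ---------------------------------------------------------------------------

def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 2.0
    a.mismatch_score = -1.0
    a.open_gap_score = -5.0
    a.extend_gap_score = -2.0
    # free end gaps
    try:
        a.end_insertion_score = 0.0
        a.end_deletion_score = 0.0
    except AttributeError:  # older attribute spelling
        a.target_end_gap_score = 0.0
        a.query_end_gap_score = 0.0
    return a


_ALIGNER = _aligner()


@lru_cache(maxsize=200_000)
def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Identity = matching columns / alignment length, free end gaps.

    Alignment length counts aligned columns plus internal gap columns;
    terminal overhangs are free and excluded.
    """
    if seq_a == seq_b:
        return 1.0
    aln = _ALIGNER.align(seq_a, seq_b)[0]
    ta, qa = aln.aligned
    matches = 0
    cols = 0
    for (ts, te), (qs, qe) in zip(ta, qa):
        cols += te - ts
        matches += sum(
            1 for x, y in zip(seq_a[ts:te], seq_b[qs:qe]) if x == y
        )
    # internal gap columns between consecutive aligned blocks
    for k in range(1, len(ta)):
        cols += (ta[k][0] - ta[k - 1][1]) + (qa[k][0] - qa[k - 1][1])
    if cols == 0:
        return 0.0
    return matches / cols


# ---------------------------------------------------------------------------
# Clustering and mapping
# ---------------------------------------------------------------------------

def cluster_otus(unique_seqs, identity: float = 0.97) -> OtuCatalog:
    """Greedy centroid clustering of dereplicated sequences.

    ``unique_seqs`` is an iterable of ``(sequence, abundance)``; processing
    order is abundance descending with lexicographic tie-break.  Each
    sequence joins the first existing centroid with pairwise identity >=
    ``identity``, otherwise founds a new centroid (which becomes an OTU
    representative).
    """
    ordered = sorted(unique_seqs, key=lambda kv: (-kv[1], kv[0]))
    reps: list[str] = []
    for seq, _ab in ordered:
        for rep in reps:
            if pairwise_identity(seq, rep) >= identity:
                break
        else:
            reps.append(seq)
    catalog = OtuCatalog()
    width = max(3, len(str(len(reps))))
    for i, rep in enumerate(reps):
        catalog.representatives[f"OTU_{i + 1:0{width}d}"] = rep
    return catalog


def assign_read(bases: str, catalog: OtuCatalog, identity: float = 0.97,
                tie_tol: float = 1e-9) -> str | None:
    """Best unique hit above threshold, or ``None`` (unassigned) on a tie."""
    best_id: float = -1.0
    second: float = -1.0
    best_otu: str | None = None
    for otu, rep in catalog.representatives.items():
        ident = pairwise_identity(bases, rep)
        if ident > best_id:
            second = best_id
            best_id, best_otu = ident, otu
        elif ident > second:
            second = ident
    if best_id < identity:
        return None
    if best_id - second <= tie_tol:
        return None
    return best_otu


def map_reads(records, catalog: OtuCatalog, identity: float = 0.97) -> OtuCatalog:
    """Count unambiguous best matches of reads to OTU representatives.

    Returns a new catalog sharing the representatives, with per-(OTU,
    sample) counts and per-sample unassigned tallies filled in.  Each read
    contributes to at most one OTU.
    """
    if not catalog.representatives:
        raise ValueError("catalog has no representatives")
    out = OtuCatalog(representatives=dict(catalog.representatives))
    # dereplicate per (sample, sequence) so each unique sequence aligns once
    tally: Counter[tuple[str, str]] = Counter(
        (r.sample_id, r.bases) for r in records
    )
    assignment: dict[str, str | None] = {}
    for (sample, bases), n in tally.items():
        if bases not in assignment:
            assignment[bases] = assign_read(bases, out, identity=identity)
        otu = assignment[bases]
        if otu is None:
            out.unassigned[sample] = out.unassigned.get(sample, 0) + n
        else:
            key = (otu, sample)
            out.counts[key] = out.counts.get(key, 0) + n
        out.unassigned.setdefault(sample, out.unassigned.get(sample, 0))
    return out


def counts_from_reads(
    sample_files: dict,
    factors: pd.DataFrame | None = None,
    min_len: int = 290,
    min_q: int = 20,
    max_frac_below: float = 0.2,
    identity: float = 0.97,
) -> tuple[CountTable, dict]:
    """Compose the full pipeline: filter -> dereplicate -> cluster -> map.

    ``sample_files`` maps sample id to a FASTA/FASTQ path.  Returns the
    CountTable (samples in mapping order) and a per-sample accounting
    report; ``input = filtered_out + assigned + unassigned`` holds for every
    sample.
    """
    if not sample_files:
        raise ValueError("at least one sample file is required")
    per_sample_reads: dict[str, list[SequenceRecord]] = {}
    report: dict = {"samples": {}, "parameters": {
        "min_len": min_len, "min_q": min_q,
        "max_frac_below": max_frac_below, "identity": identity,
    }}
    pooled: list[SequenceRecord] = []
    for sample, path in sample_files.items():
        raw = read_sequences(path, sample)
        kept = filter_reads(raw, min_len=min_len, min_q=min_q,
                            max_frac_below=max_frac_below)
        per_sample_reads[sample] = kept
        report["samples"][sample] = {
            "input": len(raw), "filtered_out": len(raw) - len(kept),
        }
        pooled.extend(kept)
    uniques = dereplicate(pooled)
    catalog = cluster_otus(uniques, identity=identity)
    if catalog.representatives:
        mapped = map_reads(pooled, catalog, identity=identity)
    else:
        mapped = catalog
    samples = list(sample_files)
    table = mapped.count_table(factors=factors, sample_ids=samples)
    for sample in samples:
        rep = report["samples"][sample]
        rep["assigned"] = int(table.counts.loc[sample].sum())
        rep["unassigned"] = int(mapped.unassigned.get(sample, 0))
    report["n_otus"] = len(catalog.representatives)
    return table, report


def read_manifest(path) -> tuple[dict, pd.DataFrame]:
    """Parse a samples manifest TSV (sample_id, file, factor columns...)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "file"):
        if col not in df.columns:
            raise ValueError(f"manifest missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in manifest")
    base = Path(path).parent
    files = {
        r.sample_id: (base / r.file if not Path(r.file).is_absolute() else Path(r.file))
        for r in df.itertuples()
    }
    factors = df.set_index("sample_id").drop(columns=["file"])
    factors.index.name = None
    return files, factors
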