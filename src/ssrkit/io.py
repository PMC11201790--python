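"""Readers and writers for the interchange formats.

FASTA goes through Biopython.  GFF3 is 1-based inclusive with a version
pragma; BED is the 0-based half-open conversion of the same spans; Newick
strings are terminated by ';'; the link file is the Circos-style
source_chr source_start source_end target_chr target_start target_end
marker_id layout.  All writers emit stable orderings so reruns are
byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field, fields as dc_fields
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Tuple

import yaml
from Bio import SeqIO

from .cluster import UPGMANode
from .errors import ParseError, ValidationError
from .mining import MiningSummary, SSRLocus
from .primers import PrimerPair
from .transfer import SyntenyLink

logger = logging.getLogger("ssrkit")


def read_fasta(path: str) -> Iterator[Tuple[str, str]]:
    """Yield (seq_id, sequence) from a (multi-)FASTA file."""
    for rec in SeqIO.parse(path, "fasta"):
        yield rec.id, str(rec.seq)


def write_fasta(sequences: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for sid in sequences:
            fh.write(f">{sid}\n")
            seq = sequences[sid]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_loci_gff3(loci: Iterable[SSRLocus], path: str, source: str = "ssrkit") -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for i, L in enumerate(sorted(loci, key=lambda x: (x.seq_id, x.start, x.period)), 1):
            attrs = (
                f"ID=ssr{i};motif={L.motif};motif_class={L.motif_class};"
                f"repeats={L.repeats}"
            )
            fh.write(
                f"{L.seq_id}\t{source}\tmicrosatellite\t{L.start}\t{L.end}\t.\t+\t.\t{attrs}\n"
            )


def read_loci_gff3(path: str) -> List[SSRLocus]:
    loci: List[SSRLocus] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for ln_no, ln in enumerate(fh, 1):
            if not ln.strip() or ln.startswith("#"):
                continue
            f = ln.rstrip("\n").split("\t")
            if len(f) != 9:
                raise ParseError(f"{path}:{ln_no}: expected 9 GFF3 columns, got {len(f)}")
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            try:
                motif = attrs["motif"]
                repeats = int(attrs["repeats"])
            except KeyError as e:
                raise ParseError(f"{path}:{ln_no}: missing attribute {e}")
            loci.append(
                SSRLocus(
                    seq_id=f[0],
                    start=int(f[3]),
                    end=int(f[4]),
                    motif=motif,
                    motif_class=attrs.get("motif_class") or motif,
                    period=len(motif),
                    repeats=repeats,
                )
            )
    return loci


def write_loci_bed(loci: Iterable[SSRLocus], path: str) -> None:
    """BED (0-based half-open) conversion of the locus spans."""
    with open(path, "wt", encoding="utf-8") as fh:
        for L in sorted(loci, key=lambda x: (x.seq_id, x.start, x.period)):
            fh.write(f"{L.seq_id}\t{L.start - 1}\t{L.end}\t{L.motif_class}x{L.repeats}\n")


def write_loci_tsv(loci: Iterable[SSRLocus], path: str) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("seq_id\tstart\tend\tmotif\tmotif_class\tperiod\trepeats\tlength\n")
        for L in sorted(loci, key=lambda x: (x.seq_id, x.start, x.period)):
            fh.write(
                f"{L.seq_id}\t{L.start}\t{L.end}\t{L.motif}\t{L.motif_class}\t"
                f"{L.period}\t{L.repeats}\t{L.length}\n"
            )


def write_mining_summary(summary: MiningSummary, path: str) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"total_count\t{summary.total_count}\n")
        fh.write(f"total_length_bp\t{summary.total_length_bp}\n")
        fh.write(f"mean_length_bp\t{summary.mean_length_bp:.2f}\n")
        fh.write(f"relative_abundance_per_mb\t{summary.relative_abundance:.2f}\n")
        fh.write(f"relative_density_bp_per_mb\t{summary.relative_density:.2f}\n")
        for p in sorted(summary.counts_by_period):
            fh.write(f"count_period_{p}\t{summary.counts_by_period[p]}\n")
        if summary.length_count_correlation is not None:
            fh.write(f"length_count_pearson_r\t{summary.length_count_correlation:.3f}\n")


def write_primer_tsv(pairs: Mapping[str, List[PrimerPair]], path: str) -> None:
    """Primer table: one row per candidate, keyed by marker id."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(
            "marker\trank\tleft_seq\tright_seq\tleft_start\tright_start\t"
            "product_bp\tleft_tm\tright_tm\tleft_gc\tright_gc\n"
        )
        for marker in sorted(pairs):
            for r, p in enumerate(pairs[marker], 1):
                fh.write(
                    f"{marker}\t{r}\t{p.left_seq}\t{p.right_seq}\t{p.left_start}\t"
                    f"{p.right_start}\t{p.product_bp}\t{p.left_tm:.2f}\t{p.right_tm:.2f}\t"
                    f"{p.left_gc:.2f}\t{p.right_gc:.2f}\n"
                )


def read_primer_tsv(path: str) -> Dict[str, List[PrimerPair]]:
    out: Dict[str, List[PrimerPair]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {h: i for i, h in enumerate(header)}
        for ln_no, ln in enumerate(fh, 2):
            if not ln.strip():
                continue
            f = ln.rstrip("\n").split("\t")
            try:
                pair = PrimerPair(
                    left_seq=f[idx["left_seq"]],
                    right_seq=f[idx["right_seq"]],
                    left_start=int(f[idx["left_start"]]),
                    right_start=int(f[idx["right_start"]]),
                    product_bp=int(f[idx["product_bp"]]),
                    left_tm=float(f[idx["left_tm"]]),
                    right_tm=float(f[idx["right_tm"]]),
                    left_gc=float(f[idx["left_gc"]]),
                    right_gc=float(f[idx["right_gc"]]),
                )
            except (KeyError, ValueError, IndexError) as e:
                raise ParseError(f"{path}:{ln_no}: {e}")
            out.setdefault(f[idx["marker"]], []).append(pair)
    return out


def write_newick(tree: UPGMANode, path: str, precision: int = 6) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(tree.newick(precision=precision) + "\n")


def write_links(links: Iterable[SyntenyLink], path: str) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for L in links:
            fh.write(
                f"{L.source_seq_id}\t{L.source_start}\t{L.source_end}\t"
                f"{L.target_seq_id}\t{L.target_start}\t{L.target_end}\t{L.marker_id}\n"
            )


def write_pair_counts(counts: Mapping[Tuple[str, str], int], path: str) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("source_chr\ttarget_chr\tn_links\n")
        for (s, t) in sorted(counts):
            fh.write(f"{s}\t{t}\t{counts[(s, t)]}\n")


# -- pipeline configuration -------------------------------------------------


@dataclass
class PipelineConfig:
    """Flat parameter block for the end-to-end pipeline.

    Round-trips losslessly through YAML; unknown keys are rejected so a
    typo cannot silently fall back to a default.
    """

    seed: int = 0
    out_dir: str = "ssrkit_out"
    min_repeats: Dict[int, int] = field(
        default_factory=lambda: {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}
    )
    product_bp: Tuple[int, int] = (100, 250)
    primer_len: Tuple[int, int] = (18, 24)
    tm_celsius: Tuple[float, float] = (50.0, 60.0)
    gc_percent: Tuple[float, float] = (40.0, 60.0)
    max_tm_diff: float = 3.0
    max_candidates: int = 3
    max_5prime_mismatches: int = 5
    three_prime_anchor_bp: int = 5
    min_identity: float = 0.90
    max_product_bp: int = 2000
    scaffold_pattern: str = r"(?i)scaffold|contig"
    similarity_method: str = "simple_matching"
    burn_in: int = 1_000
    main_iterations: int = 10_000
    replicates: int = 10
    k_min: int = 1
    k_max: int = 10
    alpha: float = 1.0
    lam: float = 1.0
    association_model: str = "both"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ParseError(f"{path}: config must be a mapping")
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParseError(f"{path}: unknown config keys: {sorted(unknown)}")
        if "min_repeats" in raw:
            raw["min_repeats"] = {int(k): int(v) for k, v in raw["min_repeats"].items()}
        for tup in ("product_bp", "primer_len", "tm_celsius", "gc_percent"):
            if tup in raw:
                raw[tup] = tuple(raw[tup])
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        data = asdict(self)
        for tup in ("product_bp", "primer_len", "tm_celsius", "gc_percent"):
            data[tup] = list(data[tup])
        with open(path, "wt", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def param_hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def log_stage(stage: str, config: PipelineConfig, inputs: Mapping[str, str]) -> None:
    """One structured log line per stage: parameter hash + input checksums."""
    sums = {}
    for name, path in inputs.items():
        try:
            with open(path, "rb") as fh:
                sums[name] = hashlib.sha256(fh.read()).hexdigest()[:12]
        except OSError:
            sums[name] = "unreadable"
    logger.info("stage=%s params=%s inputs=%s", stage, config.param_hash(), sums)
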