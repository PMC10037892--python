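"""Readers and writers for the pipeline's on-disk formats.

FASTA via Biopython; tabular outputs as TSV with an optional provenance
comment line; chromosome builds as AGP v2.1; whole-genome alignments as
PAF. Coordinates in BED/PAF/TSV outputs are 0-based half-open; AGP is
1-based inclusive as its specification requires.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .curation import Breakpoint, ChromosomeBuild, ScaffoldPart
from .errors import ParseError
from .seqs import revcomp

PAF_COLUMNS = [
    "query", "qlen", "qstart", "qend", "strand",
    "target", "tlen", "tstart", "tend", "matches", "alnlen", "mapq",
]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_tsv(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """TSV with an optional single '# key=value ...' provenance header line."""
    path = Path(path)
    with path.open("w") as fh:
        if provenance:
            fh.write("# " + " ".join(f"{k}={json.dumps(v)}" for k, v in sorted(provenance.items())) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def load_config(path) -> dict:
    """YAML (or JSON, a YAML subset) parameter file -> dict."""
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh) or {}


# ---------------------------------------------------------------------------
# scaffold truth / observations


def truth_to_frame(truths) -> pd.DataFrame:
    rows = []
    for t in truths:
        off = 0
        for i, p in enumerate(t.parts):
            rows.append(
                {
                    "scaffold_id": t.scaffold_id,
                    "part_index": i,
                    "chromosome": p.chromosome_id,
                    "start": p.start,
                    "end": p.end,
                    "strand": p.strand,
                    "scaffold_offset": off,
                }
            )
            off += p.end - p.start
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# candidates / probe windows / oligo library


def candidates_to_bed(candidates) -> pd.DataFrame:
    """BED6+ per candidate: scaffold, start, end, id, tm, strand, gc,
    max_kmer_count, hairpin_dg."""
    rows = []
    for i, c in enumerate(candidates):
        rows.append(
            {
                "chrom": c.scaffold_id,
                "start": c.start,
                "end": c.end,
                "name": f"cand_{i:06d}",
                "score": round(c.tm, 3),
                "strand": "+",
                "gc": round(c.gc, 4),
                "max_kmer_count": c.max_kmer_count if c.max_kmer_count is not None else ".",
                "hairpin_dg": round(c.hairpin_dg, 3) if c.hairpin_dg is not None else ".",
            }
        )
    return pd.DataFrame(rows)


def windows_to_bed(windows) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": w.scaffold_id,
                "start": w.start,
                "end": w.end,
                "name": w.probe_id,
                "score": len(w.oligos),
                "strand": "+",
            }
            for w in windows
        ]
    )


def oligo_library_to_frame(oligos) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "oligo_id": o.oligo_id,
                "probe_id": o.probe_id,
                "scaffold": o.scaffold_id,
                "homolog_39mer": o.homolog,
                "start": o.start,
                "end": o.end,
                "R_id": o.reverse_id,
                "F_id": o.forward_id,
                "fluorophore": o.fluorophore,
                "assembled_79mer": o.sequence,
            }
            for o in oligos
        ]
    )


def ortho_pool_to_frame(orthos) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "seq": o.seq,
                "role": o.role,
                "gc_clamp_5prime": o.gc_clamp_5prime,
                "gc_clamp_3prime": o.gc_clamp_3prime,
                "min_self_dg": o.min_self_dg,
                "min_hetero_dg": o.min_hetero_dg,
                "genome_evalue": o.genome_evalue,
            }
            for o in orthos
        ]
    )


def primers_to_frame(primers) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "primer_id": p.primer_id,
                "kind": p.kind,
                "sequence": p.sequence,
                "length": len(p.sequence),
                "fluorophore": p.fluorophore or ".",
            }
            for p in primers
        ]
    )


def plan_to_frame(plan) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "probe_id": w.probe_id,
                "scaffold_id": w.scaffold_id,
                "start": w.start,
                "end": w.end,
                "design_index": w.design_index,
                "n_oligo": len(w.oligos),
                "fluorophores": "+".join(sorted(w.fluorophores)) if w.fluorophores else ".",
            }
            for w in plan.windows
        ]
    )


def plan_from_frame(df: pd.DataFrame, scaffold_lengths: dict[str, int], n_oligo: int):
    """Rebuild a probe plan (without per-oligo detail) from its table."""
    from .design import ProbePlan, ProbeWindow

    windows = []
    for _, r in df.iterrows():
        fl = r.get("fluorophores")
        windows.append(
            ProbeWindow(
                probe_id=str(r["probe_id"]),
                scaffold_id=str(r["scaffold_id"]),
                start=int(r["start"]),
                end=int(r["end"]),
                oligos=[],
                design_index=int(r["design_index"]),
                fluorophores=None if fl in (".", None) else frozenset(str(fl).split("+")),
            )
        )
    return ProbePlan(windows, scaffold_lengths, n_oligo)


# ---------------------------------------------------------------------------
# AGP


def agp_frame(builds: list[ChromosomeBuild]) -> pd.DataFrame:
    """AGP v2.1 rows: W components interleaved with U gap rows.

    The component id is ``scaffold/part`` so that parsing an emitted AGP
    recovers the part identity; orientation '?' encodes an undetermined
    orientation."""
    rows = []
    for b in builds:
        pos = 0
        part_no = 0
        gap_type, gap_len, evidence = b.gap_policy
        for i, p in enumerate(b.parts):
            if i > 0:
                part_no += 1
                rows.append(
                    [b.chromosome_id, pos + 1, pos + gap_len, part_no,
                     gap_type, gap_len, "contig", "yes", evidence]
                )
                pos += gap_len
            part_no += 1
            rows.append(
                [b.chromosome_id, pos + 1, pos + len(p), part_no, "W",
                 f"{p.scaffold_id}/{p.part_id}", p.start + 1, p.end,
                 p.orientation if p.orientation else "?"]
            )
            pos += len(p)
    return pd.DataFrame(
        rows,
        columns=["object", "object_beg", "object_end", "part_number",
                 "component_type", "c6", "c7", "c8", "c9"],
    )


def write_agp(builds: list[ChromosomeBuild], path) -> None:
    df = agp_frame(builds)
    with Path(path).open("w") as fh:
        fh.write("##agp-version 2.1\n")
        df.to_csv(fh, sep="\t", index=False, header=False)


def parse_agp(path) -> list[ChromosomeBuild]:
    builds: dict[str, ChromosomeBuild] = {}
    gap_policy = ("U", 100, "map")
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise ParseError(f"AGP line {lineno}: expected 9 columns, got {len(f)}")
            obj, _, _, _, ctype = f[0], f[1], f[2], f[3], f[4]
            if obj not in builds:
                builds[obj] = ChromosomeBuild(obj, [], gap_policy=gap_policy)
            if ctype in ("U", "N"):
                builds[obj].gap_policy = (ctype, int(f[5]), f[8])
                continue
            if ctype != "W":
                raise ParseError(f"AGP line {lineno}: unsupported component type {ctype}")
            comp = f[5]
            scaffold_id, _, part_id = comp.partition("/")
            part = ScaffoldPart(
                part_id=part_id or comp,
                scaffold_id=scaffold_id,
                start=int(f[6]) - 1,
                end=int(f[7]),
                orientation=None if f[8] in ("?", "0", "na") else f[8],
                assigned_chromosome=obj,
                order_on_chromosome=len(builds[obj].parts),
            )
            builds[obj].parts.append(part)
    return list(builds.values())


def corrected_scaffold_fasta(scaffolds: dict[str, str], parts: list[ScaffoldPart], path) -> None:
    """Apply splits and orientations: one record per part, '-' parts
    reverse-complemented."""
    seqs = {}
    for p in parts:
        s = scaffolds[p.scaffold_id][p.start : p.end]
        seqs[p.part_id] = revcomp(s) if p.orientation == "-" else s
    write_fasta(seqs, path)


def anomaly_report(statuses: dict[str, str], breakpoints: dict[str, Breakpoint]) -> pd.DataFrame:
    rows = []
    for sid in sorted(statuses):
        bp = breakpoints.get(sid)
        rows.append(
            {
                "scaffold_id": sid,
                "status": statuses[sid],
                "breakpoint_left": bp.left_bound if bp else ".",
                "breakpoint_right": bp.right_bound if bp else ".",
                "flanking_probes": "|".join(bp.flanking_probe_ids) if bp else ".",
                "evidence": bp.evidence if bp else ".",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PAF


def read_paf(path) -> pd.DataFrame:
    rows = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ParseError(f"PAF line {lineno}: expected >= 12 columns, got {len(f)}")
            try:
                rows.append(
                    {
                        "query": f[0], "qlen": int(f[1]), "qstart": int(f[2]),
                        "qend": int(f[3]), "strand": f[4], "target": f[5],
                        "tlen": int(f[6]), "tstart": int(f[7]), "tend": int(f[8]),
                        "matches": int(f[9]), "alnlen": int(f[10]), "mapq": int(f[11]),
                    }
                )
            except ValueError as exc:
                raise ParseError(f"PAF line {lineno}: {exc}") from exc
    return pd.DataFrame(rows, columns=PAF_COLUMNS)


def write_paf(df: pd.DataFrame, path) -> None:
    df[PAF_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def blocks_to_frame(blocks) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "query_chromosome": b.query_chromosome,
                "query_start": b.query_start,
                "query_end": b.query_end,
                "reference_chromosome": b.reference_chromosome,
                "reference_start": b.reference_start,
                "reference_end": b.reference_end,
                "strand": b.strand,
                "aligned_bases": b.aligned_bases,
            }
            for b in blocks
        ]
    )
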