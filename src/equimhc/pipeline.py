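"""Pipeline orchestration: configuration, staged execution, report rendering.

A single YAML config drives the stages presence -> diversity -> recombination
-> selection -> reports.  Every report carries the tool version, a config
hash and the seed in ``#``-prefixed header lines, and reruns with the same
config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .diversity import allele_sharing, shared_counts, summarize
from .phylo import jc_distance_matrix, nj_tree
from .presence import presence_report
from .recomb import sbp_scan
from .seq_io import (
    CodonAlignment,
    LocusConfig,
    load_locus_configs,
    read_alignment,
    read_depth_table,
)
from .selection import consensus_sites, fel_sites, global_z_test, saas_report, slac_sites


class StageError(RuntimeError):
    """An error raised by a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    loci: dict[str, LocusConfig] = field(default_factory=dict)
    alignments: dict[str, str] = field(default_factory=dict)  # locus -> FASTA
    pooled: dict[str, list[str]] = field(default_factory=dict)
    depth_tables: dict[str, str] = field(default_factory=dict)  # genome -> TSV
    out_dir: str = "equimhc_out"
    seed: int = 0
    gap_policy: str = "complete-deletion"
    presence_threshold: float = 0.10
    site_p_threshold: float = 0.1
    n_boot: int = 1000
    min_partition: int = 10
    raw: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        thresholds = raw.get("thresholds", {})
        loci = load_locus_configs(path) if "loci" in raw else {}
        return cls(
            loci=loci,
            alignments=raw.get("alignments", {}),
            pooled=raw.get("pooled", {}),
            depth_tables=raw.get("depth_tables", {}),
            out_dir=raw.get("out_dir", "equimhc_out"),
            seed=int(raw.get("seed", 0)),
            gap_policy=raw.get("gap_policy", "complete-deletion"),
            presence_threshold=float(thresholds.get("presence", 0.10)),
            site_p_threshold=float(thresholds.get("site_p", 0.1)),
            n_boot=int(raw.get("n_boot", 1000)),
            min_partition=int(raw.get("min_partition", 10)),
            raw=raw,
        )

    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig,
               index: bool = False) -> None:
    header = (
        f"# equimhc {__version__}; config={config.config_hash()}; "
        f"seed={config.seed}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=index, na_rep="NA")


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute all configured stages; returns the written report paths."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    # -- presence ----------------------------------------------------------
    if config.depth_tables:
        try:
            intervals = {
                name: cfg.gene_interval
                for name, cfg in config.loci.items()
                if cfg.gene_interval is not None
            }
            tables = {
                genome: read_depth_table(path, intervals)
                for genome, path in config.depth_tables.items()
            }
            report = presence_report(tables, config.presence_threshold)
            path = out_dir / "presence.tsv"
            _write_tsv(report, path, config, index=True)
            written["presence"] = path
        except StageError:
            raise
        except Exception as exc:
            raise StageError("presence", str(exc)) from exc

    # -- alignments --------------------------------------------------------
    alignments: dict[str, CodonAlignment] = {}
    try:
        for locus, path in config.alignments.items():
            alignments[locus] = read_alignment(
                path, config.loci.get(locus), gap_policy=config.gap_policy
            )
    except Exception as exc:
        raise StageError("alignments", str(exc)) from exc
    if not alignments:
        return written

    # -- diversity + global selection ---------------------------------------
    try:
        table = summarize(alignments, config.pooled)
        ztests = {}
        for name in table["locus"]:
            aln = alignments.get(name) or _pool(alignments, config.pooled[name])
            if aln.without_stop_flagged().n_seqs >= 2:
                z = global_z_test(aln, n_boot=config.n_boot, seed=config.seed)
                ztests[name] = (z.Z, z.p_one_tailed, z.mean_dN_minus_dS)
            else:
                ztests[name] = (pd.NA, pd.NA, pd.NA)
        table["Z"] = [ztests[n][0] for n in table["locus"]]
        table["p_Z"] = [ztests[n][1] for n in table["locus"]]
        table["dN_minus_dS"] = [ztests[n][2] for n in table["locus"]]
        path = out_dir / "diversity.tsv"
        _write_tsv(table, path, config)
        written["diversity"] = path

        shared = {
            locus: list(zip(aln.species_tags, aln.seqs))
            for locus, aln in alignments.items()
        }
        sharing = allele_sharing(shared)
        sharing_path = out_dir / "allele_sharing.tsv"
        _write_tsv(sharing, sharing_path, config)
        counts_path = out_dir / "shared_counts.tsv"
        _write_tsv(shared_counts(shared).to_frame(), counts_path, config,
                   index=True)
        written["allele_sharing"] = sharing_path
        written["shared_counts"] = counts_path
    except Exception as exc:
        raise StageError("diversity", str(exc)) from exc

    # -- recombination + site-wise selection --------------------------------
    verdicts = {}
    consensus_tables = {}
    for locus, aln in alignments.items():
        work = aln.without_stop_flagged()
        if work.n_seqs < 4:
            continue
        try:
            scan = sbp_scan(work, min_partition=config.min_partition)
            verdicts[locus] = scan
            trace_path = out_dir / f"recomb_{locus}.tsv"
            _write_tsv(scan.trace, trace_path, config)
            written[f"recomb_{locus}"] = trace_path
        except Exception as exc:
            raise StageError("recomb", f"{locus}: {exc}") from exc
        try:
            parts = (
                [work.slice_codons(0, scan.best_breakpoint),
                 work.slice_codons(scan.best_breakpoint, work.n_codons)]
                if scan.best_breakpoint
                else [work]
            )
            frames_slac, frames_fel = [], []
            offset = 0
            for part in parts:
                mat, ids = jc_distance_matrix(part)
                tree = nj_tree(mat, ids)
                slac = slac_sites(part, tree, config.site_p_threshold)
                fel = fel_sites(part, tree, config.site_p_threshold)
                slac["site"] += offset
                fel["site"] += offset
                frames_slac.append(slac)
                frames_fel.append(fel)
                offset += part.n_codons
            methods = {
                "SLAC": pd.concat(frames_slac, ignore_index=True),
                "FEL": pd.concat(frames_fel, ignore_index=True),
            }
            abs_codons = (
                config.loci[locus].abs_codons if locus in config.loci else frozenset()
            )
            consensus_tables[locus] = consensus_sites(methods, abs_codons)
            path = out_dir / f"sites_{locus}.tsv"
            _write_tsv(consensus_tables[locus], path, config)
            written[f"sites_{locus}"] = path
        except Exception as exc:
            raise StageError("selection", f"{locus}: {exc}") from exc

    if consensus_tables:
        try:
            reports = saas_report(
                consensus_tables,
                {loc: alignments[loc] for loc in consensus_tables},
                {loc: (config.loci[loc].abs_codons if loc in config.loci
                       else frozenset())
                 for loc in consensus_tables},
            )
            for name, df in reports.items():
                path = out_dir / f"saas_{name}.tsv"
                _write_tsv(df, path, config)
                written[f"saas_{name}"] = path
            verdict_path = out_dir / "recomb_verdicts.json"
            with open(verdict_path, "w") as fh:
                json.dump(
                    {loc: {"breakpoint": s.best_breakpoint,
                           "delta_cAIC": s.delta_caic}
                     for loc, s in verdicts.items()},
                    fh, indent=2, sort_keys=True,
                )
            written["recomb_verdicts"] = verdict_path
        except Exception as exc:
            raise StageError("report", str(exc)) from exc
    return written


def _pool(alignments: dict[str, CodonAlignment], loci: list[str]) -> CodonAlignment:
    parts = [alignments[loc] for loc in loci]
    flagged, offset = set(), 0
    for p in parts:
        flagged.update(i + offset for i in p.stop_flagged)
        offset += p.n_seqs
    return CodonAlignment(
        ids=[i for p in parts for i in p.ids],
        seqs=[s for p in parts for s in p.seqs],
        species_tags=[t for p in parts for t in p.species_tags],
        locus_tags=[t for p in parts for t in p.locus_tags],
        gap_policy=parts[0].gap_policy,
        stop_flagged=flagged,
    )
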