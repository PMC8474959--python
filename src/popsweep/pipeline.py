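"""End-to-end orchestration: filter -> diversity -> F_ST -> AMOVA -> PCA -> sweeps.

``run_pipeline`` drives every stage from a single :class:`PipelineConfig`
(usually loaded from YAML), writes one TSV per stage, and records a
machine-readable manifest (package/library versions, parameters, input
checksums) sufficient to reproduce the run.  Identical config + seed yields
byte-identical outputs.
"""
from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import __version__
from .differentiation import amova, pairwise_fst, pca
from .diversity import population_summary
from .genotype_io import (
    GenotypeDataset,
    PopulationMap,
    read_annotation,
    read_popmap,
    read_vcf,
    filter_sites,
    write_vcf,
)
from .sweep_scan import call_selected_windows, enrich, overlap_genes, read_term2gene, window_stats

logger = logging.getLogger(__name__)


def write_table(table: pd.DataFrame, path: str | os.PathLike, command: str) -> None:
    """Write a TSV with a leading comment naming the generating command."""
    with open(path, "w") as fh:
        fh.write(f"# {command}\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def parse_grouping(text: str) -> list[list[str]]:
    """Parse a bracket grouping like ``[N1; N2; N3] [H1] [S1; S2]``."""
    groups = []
    rest = text.strip()
    while rest:
        if not rest.startswith("["):
            raise ValueError(f"expected '[' in grouping near {rest[:20]!r}")
        close = rest.index("]")
        inner = rest[1:close]
        members = [p.strip() for p in inner.replace(",", ";").split(";") if p.strip()]
        if not members:
            raise ValueError("empty group in grouping expression")
        groups.append(members)
        rest = rest[close + 1:].strip()
    if not groups:
        raise ValueError("no groups parsed from grouping expression")
    return groups


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class PipelineConfig:
    """Inputs, thresholds, and design for a full analysis run."""

    vcf: str
    popmap: str
    outdir: str
    seed: int
    genes: str | None = None
    term2gene: str | None = None
    maf_min: float = 0.05
    int_min: float = 0.5
    groupings: list[list[list[str]]] = field(default_factory=list)
    contrasts: list[tuple[str, str]] = field(default_factory=list)
    window_size: int = 10_000
    fst_quantile: float = 0.95
    ratio_tail: float = 0.05
    min_snps: int = 2
    n_perm: int = 10_000
    surveyed_length: float | None = None
    enrich_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["contrasts"] = [tuple(c) for c in raw.get("contrasts", [])]
        return cls(**raw)

    def validate(self, popmap: PopulationMap) -> None:
        known_pops = set(popmap.populations)
        known_groups = set(popmap.groups)
        for grouping in self.groupings:
            pops = [p for g in grouping for p in g]
            unknown = set(pops) - known_pops
            if unknown:
                raise ValueError(f"grouping references undefined population(s): {sorted(unknown)}")
            if sorted(pops) != sorted(known_pops):
                raise ValueError("each grouping must partition all populations")
        for a, b in self.contrasts:
            for g in (a, b):
                if g not in known_groups:
                    raise ValueError(f"contrast references undefined group {g!r}")


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run every configured stage; returns a name -> path map of outputs."""
    os.makedirs(config.outdir, exist_ok=True)
    log_path = os.path.join(config.outdir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("popsweep")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    outputs: dict[str, str] = {"log": log_path}
    stage = "load"
    try:
        popmap = read_popmap(config.popmap)
        config.validate(popmap)
        dataset = read_vcf(config.vcf)
        popmap.validate_dataset(dataset)

        stage = "filter"
        dataset, report = filter_sites(dataset, config.maf_min, config.int_min)
        filtered_vcf = os.path.join(config.outdir, "filtered.vcf")
        write_vcf(dataset, filtered_vcf)
        outputs["filtered_vcf"] = filtered_vcf
        logger.info("filter: retained %d/%d sites", report.n_retained, report.n_input)

        stage = "diversity"
        div = population_summary(dataset, popmap, config.surveyed_length)
        path = os.path.join(config.outdir, "diversity.tsv")
        write_table(div, path, "popsweep diversity")
        outputs["diversity"] = path

        stage = "fst"
        fst = pairwise_fst(dataset, popmap)
        path = os.path.join(config.outdir, "fst.tsv")
        frame = fst.to_frame().reset_index(names="population")
        write_table(frame, path, "popsweep fst")
        outputs["fst"] = path

        groupings = config.groupings or [[[p] for p in popmap.populations]]
        for i, grouping in enumerate(groupings, start=1):
            stage = f"amova[{i}]"
            res = amova(dataset, popmap, grouping, n_perm=config.n_perm, seed=config.seed)
            path = os.path.join(config.outdir, f"amova_{i}.tsv")
            label = " ".join("[" + "; ".join(g) + "]" for g in grouping)
            write_table(res.to_frame(), path,
                        f"popsweep amova --grouping '{label}' --n-perm {config.n_perm} "
                        f"--seed {config.seed}")
            outputs[f"amova_{i}"] = path

        stage = "pca"
        pc = pca(dataset)
        coords = pd.DataFrame(
            pc.coords,
            columns=[f"PC{i + 1}" for i in range(pc.coords.shape[1])],
        )
        coords.insert(0, "sample", dataset.samples)
        coords.insert(1, "population", [popmap.sample_population[s] for s in dataset.samples])
        path = os.path.join(config.outdir, "pca_coords.tsv")
        write_table(coords, path, "popsweep pca")
        outputs["pca_coords"] = path
        eig = pd.DataFrame(
            {"axis": [f"PC{i + 1}" for i in range(len(pc.eigenvalues))],
             "eigenvalue": pc.eigenvalues, "proportion": pc.explained}
        )
        path = os.path.join(config.outdir, "pca_eigenvalues.tsv")
        write_table(eig, path, "popsweep pca")
        outputs["pca_eigenvalues"] = path

        genes = read_annotation(config.genes) if config.genes else None
        term2gene = read_term2gene(config.term2gene) if config.term2gene else None
        for a, b in config.contrasts:
            stage = f"sweep[{a}-vs-{b}]"
            stats = window_stats(dataset, popmap, a, b,
                                 window_size=config.window_size, min_snps=config.min_snps)
            call = call_selected_windows(stats, config.fst_quantile, config.ratio_tail)
            tag = f"{a}_vs_{b}"
            cmd = (f"popsweep sweep --group-a {a} --group-b {b} "
                   f"--window-size {config.window_size} --fst-quantile {config.fst_quantile} "
                   f"--ratio-tail {config.ratio_tail} --min-snps {config.min_snps}")
            path = os.path.join(config.outdir, f"sweep_{tag}.windows.tsv")
            write_table(stats, path, cmd)
            outputs[f"sweep_{tag}_windows"] = path
            path = os.path.join(config.outdir, f"sweep_{tag}.selected.tsv")
            write_table(call.selected, path, cmd)
            outputs[f"sweep_{tag}_selected"] = path
            logger.info(
                "sweep %s: fst cutoff %.6g, ratio tails (%.6g, %.6g), %d selected windows",
                tag, call.fst_cutoff, call.ratio_lower, call.ratio_upper, len(call.selected),
            )
            if genes is not None:
                candidates = overlap_genes(call, genes)
                path = os.path.join(config.outdir, f"sweep_{tag}.genes.tsv")
                write_table(candidates, path, cmd)
                outputs[f"sweep_{tag}_genes"] = path
                if term2gene is not None and not candidates.empty:
                    stage = f"enrich[{tag}]"
                    universe = list(genes.genes["gene_id"])
                    enr = enrich(candidates["gene_id"].unique(), universe, term2gene,
                                 alpha=config.enrich_alpha)
                    path = os.path.join(config.outdir, f"enrich_{tag}.tsv")
                    write_table(enr, path, cmd)
                    outputs[f"enrich_{tag}"] = path

        stage = "manifest"
        manifest = {
            "popsweep_version": __version__,
            "parameters": {
                k: v for k, v in vars(config).items()
            },
            "inputs": {
                name: {"path": p, "sha256": _sha256(p)}
                for name, p in (("vcf", config.vcf), ("popmap", config.popmap),
                                ("genes", config.genes), ("term2gene", config.term2gene))
                if p
            },
            "outputs": outputs,
            "n_sites_filtered": report.n_retained,
        }
        path = os.path.join(config.outdir, "manifest.json")
        with open(path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        outputs["manifest"] = path
    except Exception as exc:
        incomplete = os.path.join(config.outdir, "INCOMPLETE")
        with open(incomplete, "w") as fh:
            fh.write(f"pipeline failed at stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage}: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return outputs
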