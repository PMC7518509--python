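"""Delimited-text writers for input bundles and run artifacts.

Outputs are written to a temporary sibling directory and atomically moved
into place, so a failed run leaves no partial artifacts.
"""

from __future__ import annotations

import hashlib
import os
import shutil
import tempfile
from dataclasses import asdict

import yaml

from . import __version__
from .pipeline import PipelineResult
from .synthetic import SyntheticInputs


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class atomic_dir:
    """Write into a temp dir; move it to ``target`` only on clean exit."""

    def __init__(self, target: str):
        self.target = target

    def __enter__(self) -> str:
        os.makedirs(os.path.dirname(os.path.abspath(self.target)), exist_ok=True)
        self.tmp = tempfile.mkdtemp(prefix=".mapsd-", dir=os.path.dirname(os.path.abspath(self.target)))
        return self.tmp

    def __exit__(self, exc_type, exc, tb) -> None:
        if exc_type is None:
            if os.path.isdir(self.target):
                shutil.rmtree(self.target)
            os.replace(self.tmp, self.target)
        else:
            shutil.rmtree(self.tmp, ignore_errors=True)


def write_bundle(inputs: SyntheticInputs, outdir: str) -> list[str]:
    """Emit the exact delimited formats the loaders consume, plus a manifest."""
    with atomic_dir(outdir) as tmp:
        edge_path = os.path.join(tmp, "edges.tsv")
        with open(edge_path, "w") as fh:
            for i, j in sorted(inputs.network.edges):
                fh.write(f"{inputs.network.nodes[i]}\t{inputs.network.nodes[j]}\n")
        loc_path = os.path.join(tmp, "localization.tsv")
        with open(loc_path, "w") as fh:
            for node in sorted(inputs.localization.assignments):
                for dom in sorted(inputs.localization.domains_of(node)):
                    fh.write(f"{node}\t{dom}\n")
        ab_path = os.path.join(tmp, "abundance.tsv")
        inputs.abundance.to_csv(ab_path, sep="\t", index=False)
        cat_path = os.path.join(tmp, "catalog.tsv")
        brain = set(inputs.catalog.brain_columns)
        with open(cat_path, "w") as fh:
            fh.write("tissue\tcell_type\tis_brain\n")
            for col in inputs.catalog.columns:
                fh.write(f"{col[0]}\t{col[1]}\t{int(col in brain)}\n")
        ev_dir = os.path.join(tmp, "evidence")
        os.makedirs(ev_dir)
        for layer, genes in inputs.layer_gene_lists.items():
            with open(os.path.join(ev_dir, f"{layer}.txt"), "w") as fh:
                fh.writelines(f"{g}\n" for g in sorted(genes))
        manifest = {
            "spec": asdict(inputs.spec) if inputs.spec is not None else None,
            "module_genes": inputs.module_genes,
            "seed_genes": inputs.seed_genes,
            "version": __version__,
        }
        with open(os.path.join(tmp, "manifest.yaml"), "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
    return sorted(os.listdir(outdir))


def write_results(result: PipelineResult, outdir: str,
                  input_paths: dict[str, str] | None = None) -> None:
    """Write the diffused matrix, diagnostics, ranked table, and run manifest."""
    with atomic_dir(outdir) as tmp:
        labels = result.diffusion.smoothed.catalog.labels()
        with open(os.path.join(tmp, "diffused_matrix.tsv"), "w") as fh:
            fh.write("gene_id\t" + "\t".join(labels) + "\n")
            for gene, row in zip(result.universe, result.diffusion.smoothed.values):
                fh.write(gene + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
        with open(os.path.join(tmp, "diagnostics.tsv"), "w") as fh:
            fh.write("t\tSSE\tSST\tR\n")
            for t, sse, sst, r in result.diffusion.diagnostics.steps:
                fh.write(f"{t}\t{sse:.10g}\t{sst:.10g}\t{r:.10g}\n")
        result.ranked.table.to_csv(os.path.join(tmp, "ranked_genes.tsv"),
                                   sep="\t", index=False)
        manifest = {
            "config": {
                "amplification": result.config.amplification,
                "missing_weight": result.config.missing_weight,
                "r_threshold": result.config.r_threshold,
                "t_max": result.config.t_max,
                "orientation": result.config.orientation,
                "uniform_weights": result.config.uniform_weights,
            },
            "t_stop": result.diffusion.t_stop,
            "capped": result.diffusion.capped,
            "n_genes": len(result.universe),
            "n_isolated": len(result.isolated_nodes),
            "input_checksums": {k: _checksum(p) for k, p in (input_paths or {}).items()},
            "version": __version__,
        }
        with open(os.path.join(tmp, "manifest.yaml"), "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
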