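"""Synthetic multi-batch single-cell count data with ground truth.

Generative model, per cell:

* every cell type has a baseline log-mean expression vector with a block
  of elevated marker genes;
* each subtype adds Normal(0, subtype_shift_sd) log-offsets on a random
  gene subset, giving hierarchical structure;
* each batch multiplies every gene's rate by exp(Normal(0, batch_effect_sd));
* gene rates are renormalized to proportions, scaled by a log-normal
  library size, and counts drawn from a gamma-Poisson (negative binomial
  with a single shared dispersion).

Reference and query domains share some types and each carry exclusive
("interfering") ones; query ground truth is kept in separate truth tables
so it can never leak into model inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data import AnnotatedMatrix


@dataclass
class SimConfig:
    n_types_shared: int = 4
    n_types_ref_only: int = 0
    n_types_query_only: int = 0
    subtypes_per_type: int = 1
    n_genes: int = 300
    n_marker_genes_per_type: int = 20
    cells_per_type_per_batch: int = 100
    n_ref_batches: int = 2
    n_query_batches: int = 2
    batch_effect_sd: float = 0.0
    subtype_shift_sd: float = 0.4
    dispersion: float = 2.0          # NB: var = mu + mu^2 / dispersion
    marker_log_fc: float = 2.0
    library_size: float = 2000.0
    library_size_sd: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.n_types_shared + self.n_types_ref_only < 1:
            raise ValueError("need at least one reference cell type")
        if self.n_genes < 1 or self.cells_per_type_per_batch < 1:
            raise ValueError("n_genes and cells_per_type_per_batch must be >= 1")
        if self.n_marker_genes_per_type * self.total_types > self.n_genes:
            raise ValueError("not enough genes for disjoint marker blocks")

    @property
    def total_types(self) -> int:
        return self.n_types_shared + self.n_types_ref_only + self.n_types_query_only


def _nb_counts(mu: np.ndarray, dispersion: float,
               rng: np.random.Generator) -> np.ndarray:
    """Gamma-Poisson sampling of a negative binomial with shared dispersion."""
    lam = rng.gamma(shape=dispersion, scale=mu / dispersion)
    return rng.poisson(lam)


def simulate(cfg: SimConfig) -> tuple[AnnotatedMatrix, AnnotatedMatrix, dict]:
    """Generate (reference, query, truth) from ``cfg``. Reference labels are
    at subtype resolution when ``subtypes_per_type > 1``; query labels are
    withheld from the returned matrix and live only in the truth tables."""
    rng = np.random.default_rng(cfg.seed)
    genes = [f"gene{i:04d}" for i in range(cfg.n_genes)]

    type_names, status = [], []
    for i in range(cfg.n_types_shared):
        type_names.append(f"shared_{i}")
        status.append("shared")
    for i in range(cfg.n_types_ref_only):
        type_names.append(f"ref_only_{i}")
        status.append("ref_only")
    for i in range(cfg.n_types_query_only):
        type_names.append(f"query_only_{i}")
        status.append("query_only")

    base = rng.normal(0.0, 0.3, size=cfg.n_genes)
    marker_rows = []
    type_logmean = {}
    for t, name in enumerate(type_names):
        lm = base.copy()
        block = np.arange(t * cfg.n_marker_genes_per_type,
                          (t + 1) * cfg.n_marker_genes_per_type)
        lm[block] += cfg.marker_log_fc
        type_logmean[name] = lm
        marker_rows += [{"gene": genes[g], "type": name} for g in block]

    subtype_logmean = {}
    subtype_parent = {}
    for name in type_names:
        for s in range(cfg.subtypes_per_type):
            sub = f"{name}.s{s}" if cfg.subtypes_per_type > 1 else name
            lm = type_logmean[name].copy()
            if cfg.subtypes_per_type > 1:
                touched = rng.choice(cfg.n_genes, size=min(30, cfg.n_genes),
                                     replace=False)
                lm[touched] += rng.normal(0.0, cfg.subtype_shift_sd, size=touched.size)
            subtype_logmean[sub] = lm
            subtype_parent[sub] = name

    batch_names = [f"ref_b{i}" for i in range(cfg.n_ref_batches)] + \
                  [f"query_b{i}" for i in range(cfg.n_query_batches)]
    batch_effect = {b: rng.normal(0.0, cfg.batch_effect_sd, size=cfg.n_genes)
                    for b in batch_names}

    def _domain_types(domain: str) -> list[str]:
        drop = "query_only" if domain == "reference" else "ref_only"
        return [n for n, s in zip(type_names, status) if s != drop]

    def _make(domain: str, batches: list[str], prefix: str):
        counts_rows, cell_ids, batch_col, type_col, subtype_col = [], [], [], [], []
        i = 0
        for b in batches:
            for name in _domain_types(domain):
                subs = [s for s, p in subtype_parent.items() if p == name]
                for cell in range(cfg.cells_per_type_per_batch):
                    sub = subs[rng.integers(len(subs))]
                    rate = np.exp(subtype_logmean[sub] + batch_effect[b])
                    prop = rate / rate.sum()
                    lib = np.exp(rng.normal(np.log(cfg.library_size),
                                            cfg.library_size_sd))
                    counts_rows.append(_nb_counts(lib * prop, cfg.dispersion, rng))
                    cell_ids.append(f"{prefix}{i:05d}")
                    batch_col.append(b)
                    type_col.append(name)
                    subtype_col.append(sub)
                    i += 1
        counts = np.vstack(counts_rows)
        return counts, cell_ids, batch_col, type_col, subtype_col

    r_counts, r_cells, r_batch, r_type, r_sub = _make(
        "reference", batch_names[:cfg.n_ref_batches], "ref_")
    q_counts, q_cells, q_batch, q_type, q_sub = _make(
        "query", batch_names[cfg.n_ref_batches:], "query_")

    ref_label = r_sub if cfg.subtypes_per_type > 1 else r_type
    ref = AnnotatedMatrix(counts=r_counts, gene_ids=genes, cell_ids=r_cells,
                          batch=r_batch, label=ref_label)
    query = AnnotatedMatrix(counts=q_counts, gene_ids=genes, cell_ids=q_cells,
                            batch=q_batch, label=None)

    truth = {
        "cells": pd.DataFrame({
            "cell_id": r_cells + q_cells,
            "domain": ["reference"] * len(r_cells) + ["query"] * len(q_cells),
            "batch": r_batch + q_batch,
            "type": r_type + q_type,
            "subtype": r_sub + q_sub,
        }),
        "types": pd.DataFrame({"type": type_names, "status": status}),
        "markers": pd.DataFrame(marker_rows),
    }
    return ref, query, truth


def fixture_presets() -> dict[str, SimConfig]:
    """Named configurations emulating the experimental designs at desk scale."""
    base = SimConfig()
    return {
        # full overlap, no batch effect: any competent classifier should excel
        "easy": replace(base, n_types_shared=4, batch_effect_sd=0.0,
                        n_ref_batches=1, n_query_batches=1,
                        cells_per_type_per_batch=150, n_genes=300),
        # one interfering type on each side, ~6000 cells total
        "partial_overlap": replace(base, n_types_shared=5, n_types_ref_only=1,
                                   n_types_query_only=1, n_genes=400,
                                   cells_per_type_per_batch=250,
                                   n_ref_batches=2, n_query_batches=2,
                                   batch_effect_sd=0.3),
        # fine reference labels, coarse query truth
        "resolution_mismatch": replace(base, n_types_shared=4,
                                       subtypes_per_type=3, n_genes=400,
                                       subtype_shift_sd=0.8,
                                       cells_per_type_per_batch=150,
                                       batch_effect_sd=0.2),
        # large query-only fraction (5 of 8 query types ~= 63%), strong shift
        "cross_species": replace(base, n_types_shared=3, n_types_query_only=5,
                                 n_genes=400, batch_effect_sd=0.6,
                                 cells_per_type_per_batch=120,
                                 marker_log_fc=1.5),
    }


def write_simulation(ref: AnnotatedMatrix, query: AnnotatedMatrix, truth: dict,
                     out_dir: str) -> None:
    import json
    import os

    from .io import write_mtx_dir

    write_mtx_dir(ref, os.path.join(out_dir, "reference"))
    write_mtx_dir(query, os.path.join(out_dir, "query"))
    for name, table in truth.items():
        table.to_csv(os.path.join(out_dir, f"truth_{name}.tsv"), sep="\t", index=False)
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump({name: table.to_dict(orient="records")
                   for name, table in truth.items()}, fh, indent=1)
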