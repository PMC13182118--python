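"""One-shot orchestration: filter -> annotate -> EM -> protein calls -> reports.

`run_pipeline` wires the stage modules together for a VCF + panel + gene
models + catalog input set and writes every tabular output to a directory,
returning a machine-readable run report. Each stage is also usable on its
own through the underlying modules.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .errors import MilkvarError
from .gene_models import (
    GeneModel,
    RegionCategory,
    read_gene_models,
    validate_gene_sizes,
)
from .haplotype_em import (
    GenotypeMatrix,
    assign_best_pairs,
    em_by_breed,
    em_estimate,
    expected_occurrences,
    hard_occurrences,
)
from .population_summary import (
    breed_frequencies,
    frequency_tables_to_frame,
    functional_report,
    variant_frequency_table,
    variant_type_table,
)
from .protein_variants import (
    Catalog,
    format_substitutions,
    haplotype_to_substitutions,
    name_variants,
)
from .variant_filtering import (
    SamplePanel,
    apply_filters,
    flag_low_depth,
    label_novelty,
    read_known_ids,
    read_vcf,
    variants_to_records,
    write_vcf,
)
from .variant_network import build_network, export_network


@dataclass
class RunConfig:
    """Paths, thresholds and toggles for a pipeline run.

    Threshold defaults are the standard milk-protein survey criteria:
    >=3 alt-supporting reads, QUAL >= 20, MQ >= 20, >=2 carrier individuals,
    genotype-depth flag below 6, and breed-level functional reporting from 20
    animals. Path fields also accept already-loaded objects.
    """

    vcf: str = ""
    panel: Union[str, SamplePanel] = ""
    gene_models: Union[str, dict[str, GeneModel]] = ""
    catalog: Union[str, Catalog, None] = None
    known_ids: Optional[str] = None
    out_dir: str = "milkvar_out"

    min_alt_reads: int = 3
    min_qual: float = 20.0
    min_mq: float = 20.0
    min_carriers: int = 2
    depth_flag_threshold: int = 6
    breed_report_min_animals: int = 20
    breed_min_samples: int = 2

    em_tol: float = 1e-8
    em_max_iter: int = 1000
    seed: int = 0

    missense_only: bool = True
    posterior_occurrences: bool = False


def _load(cfg: RunConfig):
    panel = cfg.panel if isinstance(cfg.panel, SamplePanel) else SamplePanel.from_tsv(cfg.panel)
    models = (
        cfg.gene_models
        if isinstance(cfg.gene_models, dict)
        else read_gene_models(cfg.gene_models)
    )
    if isinstance(cfg.catalog, Catalog):
        catalog = cfg.catalog.copy()
    elif cfg.catalog:
        catalog = Catalog.from_tsv(cfg.catalog)
    else:
        catalog = Catalog()
        for m in models.values():
            catalog.add_gene(m.name, m.reference_variant_name)
    return panel, models, catalog


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline and write outputs under ``cfg.out_dir``.

    Returns the run report (also written as ``run_report.json``): stage
    counts, per-gene summaries, configuration echo and package version.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    panel, models, catalog = _load(cfg)
    report: dict = {
        "version": __version__,
        "config": {
            k: v
            for k, v in vars(cfg).items()
            if isinstance(v, (int, float, str, bool, type(None)))
        },
        "gene_size_notes": validate_gene_sizes(models),
        "stages": {},
        "genes": {},
    }

    # ---- read + filter ----------------------------------------------------
    variants, read_stats = read_vcf(cfg.vcf, panel, list(models.values()))
    report["stages"]["read"] = vars(read_stats)
    fres = apply_filters(
        variants,
        min_alt_reads=cfg.min_alt_reads,
        min_qual=cfg.min_qual,
        min_mq=cfg.min_mq,
        min_carriers=cfg.min_carriers,
    )
    assert len(fres.kept) + len(fres.removed) == len(variants)
    report["stages"]["filter"] = {
        "input": len(variants),
        "kept": len(fres.kept),
        "removed": len(fres.removed),
    }
    fres.removal_ledger().to_csv(
        os.path.join(cfg.out_dir, "removal_ledger.tsv"), sep="\t", index=False
    )
    write_vcf(
        os.path.join(cfg.out_dir, "filtered.vcf"),
        panel.samples,
        variants_to_records(fres.kept),
        sorted({v.chrom for v in fres.kept}),
    )
    depth_flags = {v.key: d for v, d in zip(fres.kept, flag_low_depth(fres.kept, cfg.depth_flag_threshold))}
    if cfg.known_ids:
        novelty = dict(zip((v.key for v in fres.kept), label_novelty(fres.kept, read_known_ids(cfg.known_ids))))
    else:
        novelty = {}

    # ---- annotate ---------------------------------------------------------
    ann_rows = []
    categories = []
    by_gene: dict[str, list] = {g: [] for g in models}
    for v in fres.kept:
        model = models[v.gene]
        cat = model.classify_region(v.pos, v.ref, v.alt)
        categories.append(cat)
        by_gene[v.gene].append((v, cat))
        ann_rows.append(
            {
                "variant": v.key,
                "gene": v.gene,
                "category": cat.value,
                "cds_offset": model.genomic_to_cds(v.pos),
                "mean_depth": depth_flags[v.key].mean_depth,
                "n_low_depth": depth_flags[v.key].n_flagged,
                "novelty": novelty.get(v.key, ""),
            }
        )
    pd.DataFrame(ann_rows).to_csv(
        os.path.join(cfg.out_dir, "annotations.tsv"), sep="\t", index=False
    )
    composition = variant_type_table(categories)
    composition.to_frame().to_csv(
        os.path.join(cfg.out_dir, "composition.tsv"), sep="\t", index=False
    )
    report["stages"]["annotate"] = {
        "within_gene": composition.total_within_gene,
        "upstream": composition.upstream,
        "downstream": composition.downstream,
    }

    # ---- per-gene EM, protein calls, networks -----------------------------
    hap_frames, pair_rows, variant_rows, freq_tables_all = [], [], [], []
    tables_by_gene: dict[str, list] = {}
    panel_counts = panel.breed_counts()
    use_cats = {RegionCategory.MISSENSE} if cfg.missense_only else {
        RegionCategory.MISSENSE,
        RegionCategory.SYNONYMOUS,
    }
    for gene, model in models.items():
        pairs = [(v, c) for v, c in by_gene[gene]]
        coding = [v for v, c in pairs if c in use_cats]
        coding.sort(key=lambda v: model.genomic_to_cds(v.pos))
        offsets = [model.genomic_to_cds(v.pos) for v in coding]
        gm = GenotypeMatrix.from_variants(coding, panel, cds_offsets=offsets)
        cohort = em_estimate(gm, tol=cfg.em_tol, max_iter=cfg.em_max_iter)
        per_breed = em_by_breed(
            gm, cohort, min_samples=cfg.breed_min_samples, tol=cfg.em_tol, max_iter=cfg.em_max_iter
        )
        assignments = assign_best_pairs(gm, cohort)
        occ = hard_occurrences(assignments)
        if cfg.posterior_occurrences:
            occ_soft = expected_occurrences(gm, cohort)
        hap_frames.append(cohort.to_frame("cohort").assign(gene=gene))
        for breed, est in per_breed.items():
            hap_frames.append(est.to_frame(breed).assign(gene=gene))
        for a in assignments:
            pair_rows.append(
                {
                    "sample": a.sample,
                    "breed": a.breed,
                    "gene": gene,
                    "hap1": a.pair[0],
                    "hap2": a.pair[1],
                    "posterior": a.posterior,
                }
            )

        site_infos = gm.sites
        # haplotypes observed = hard-assigned at least once, or estimated above
        # the sub-singleton cutoff (half a chromosome copy); drops numerical dust
        cut = 1.0 / (2 * cohort.n_chromosomes) if cohort.n_chromosomes else 0.0
        observed = sorted(
            set(occ) | {h for h, f in cohort.frequencies.items() if f >= cut}
        )
        hap_subs = {h: haplotype_to_substitutions(model, h, site_infos) for h in observed}
        carriers = {h: sum(1 for a in assignments if h in a.pair) for h in observed}
        pvs = name_variants(
            gene,
            hap_subs,
            occ,
            catalog,
            carriers=carriers,
            min_copies=2,
            min_carriers=2,
        )
        # low-confidence flag: any supporting genotype under the depth threshold
        flagged_samples_by_site = {
            i: depth_flags[v.key].low_confidence for i, v in enumerate(coding)
        }
        sample_index = {s: i for i, s in enumerate(panel.samples)}
        low_conf_haps = set()
        for a in assignments:
            si = sample_index[a.sample]
            for h in a.pair:
                for j, allele in enumerate(h):
                    if allele == "1" and flagged_samples_by_site[j][si]:
                        low_conf_haps.add(h)
        hap_to_name = {}
        for pv in pvs:
            for h in observed:
                if hap_subs[h] == pv.substitutions:
                    hap_to_name[h] = pv.name
            pv.low_confidence = any(
                h in low_conf_haps for h, n in hap_to_name.items() if n == pv.name
            )
            row = {
                "gene": gene,
                "name": pv.name,
                "substitutions": format_substitutions(pv.substitutions),
                "status": pv.status,
                "occurrences": pv.occurrences,
                "low_confidence": pv.low_confidence,
                "unconfirmed": pv.unconfirmed,
            }
            if cfg.posterior_occurrences:
                row["expected_occurrences"] = sum(
                    occ_soft.get(h, 0.0) for h, n in hap_to_name.items() if n == pv.name
                )
            variant_rows.append(row)

        tables = [variant_frequency_table(gene, "cohort", cohort, hap_to_name)]
        tables += breed_frequencies(gene, per_breed, hap_to_name)
        tables_by_gene[gene] = tables
        freq_tables_all.extend(tables)

        net = build_network([pv for pv in pvs], catalog, gene)
        export_network(net, os.path.join(cfg.out_dir, f"network_{gene}.graphml"), "graphml")
        export_network(net, os.path.join(cfg.out_dir, f"network_{gene}.tsv"), "tsv")
        report["genes"][gene] = {
            "haplotype_sites": len(coding),
            "dropped_individuals": gm.n_dropped,
            "em_iterations": cohort.iterations,
            "em_converged": cohort.converged,
            "n_haplotypes": sum(1 for f in cohort.frequencies.values() if f > 1e-12),
            "n_protein_variants": len(pvs),
            "n_known": sum(1 for pv in pvs if pv.status == "known"),
            "n_novel": sum(1 for pv in pvs if pv.status == "novel"),
            "network_nodes": net.number_of_nodes(),
            "network_edges": net.number_of_edges(),
        }

    pd.concat(hap_frames, ignore_index=True).to_csv(
        os.path.join(cfg.out_dir, "haplotype_frequencies.tsv"), sep="\t", index=False
    )
    pd.DataFrame(pair_rows).to_csv(
        os.path.join(cfg.out_dir, "pair_assignments.tsv"), sep="\t", index=False
    )
    pd.DataFrame(variant_rows).to_csv(
        os.path.join(cfg.out_dir, "protein_variants.tsv"), sep="\t", index=False
    )
    frequency_tables_to_frame(freq_tables_all).to_csv(
        os.path.join(cfg.out_dir, "variant_frequencies.tsv"), sep="\t", index=False
    )
    functional_report(
        tables_by_gene, catalog, models, panel_counts, cfg.breed_report_min_animals
    ).to_csv(os.path.join(cfg.out_dir, "functional_report.tsv"), sep="\t", index=False)
    catalog.to_tsv(os.path.join(cfg.out_dir, "catalog_extended.tsv"))

    with open(os.path.join(cfg.out_dir, "run_report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
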