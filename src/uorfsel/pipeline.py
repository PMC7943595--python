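"""End-to-end orchestration: simulate -> annotate -> analyses, with a manifest.

``run_pipeline`` chains every stage on a synthetic dataset and records all
inputs, seeds, parameters and output SHA-256 hashes in ``manifest.json``;
re-running from the manifest reproduces byte-identical outputs.  Result
tables are keyed by the analysis class labels (all_uorf, utc_all, utc_uaa,
stop_strengthen, start_disrupt, start_maintain, uorf_missense,
uorf_synonymous, optimality_increasing, optimality_decreasing) so the score
panels can be rebuilt as plain tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import consequence as cq
from . import conservation as cons
from . import stop_usage as su
from .genomic_model import (
    context_from_genome,
    qc_filter,
    read_csc_table,
    read_fasta,
    read_orf_bed,
    read_utr_bed,
    read_variants_vcf,
    write_csc_table,
    write_conservation_bedgraph,
    write_fasta,
    write_orf_bed,
    write_utr_bed,
)
from .maps import MapsModel, MutationRateTable, maps_pvalue, match_by_context
from .phewas import burden_collapse, logistic_assoc, phewas_thresholds, run_phewas
from .synthetic_data import (
    SimulationConfig,
    make_csc_table,
    make_rate_table,
    make_transcriptome,
    simulate_biobank,
    simulate_conservation,
    simulate_variants,
    write_biobank,
    write_vcf,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Simulation conditions plus analysis resampling budgets."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    maps_n_boot: int = 2000
    usage_n_iter: int = 2000
    conservation_n_iter: int = 2000
    ci_percentiles: tuple[float, float] = (5.0, 95.0)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**{
            **raw.get("simulation", {}),
            **{
                k: tuple(v)
                for k, v in raw.get("simulation", {}).items()
                if k in ("utr_length_range", "uorf_codon_range", "rate_range")
            },
        })
        return cls(
            simulation=sim,
            maps_n_boot=raw.get("maps_n_boot", 2000),
            usage_n_iter=raw.get("usage_n_iter", 2000),
            conservation_n_iter=raw.get("conservation_n_iter", 2000),
            ci_percentiles=tuple(raw.get("ci_percentiles", (5.0, 95.0))),
        )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def simulate_stage(config: PipelineConfig, outdir: str) -> dict:
    """Generate and write every pipeline input; returns the file map."""
    sim = config.simulation
    os.makedirs(outdir, exist_ok=True)
    genome, utrs, orfs = make_transcriptome(sim)
    rates = make_rate_table(sim)
    csc = make_csc_table(sim)
    variants, truth = simulate_variants(sim, orfs, utrs, rates, genome)

    # designated conservation classes from the planted frames
    stop_pos = [
        (p.chrom, p.pos) for o in orfs for p in cq.find_potential_stop_positions(o)
    ]
    start_pos = [
        (p.chrom, p.pos)
        for o in orfs
        for p in cq.find_start_disrupting_positions(o, in_frame=True)
    ]
    utr_positions = [
        (u.chrom, int(p)) for u in utrs for p in u.genomic_positions()
    ]
    track = simulate_conservation(
        sim,
        {"stop_creating": stop_pos, "start_disrupt": start_pos},
        utr_positions,
    )
    biobank, bb_truth = simulate_biobank(sim)

    files = {
        "genome": "genome.fa",
        "orfs": "orfs.bed",
        "utrs": "utrs.bed",
        "variants": "variants.vcf",
        "truth": "variant_truth.tsv",
        "rates": "mutation_rates.tsv",
        "csc": "csc.tsv",
        "phylop": "phylop.bedgraph",
        "biobank_truth": "biobank_truth.tsv",
    }
    write_fasta(os.path.join(outdir, files["genome"]), genome)
    write_orf_bed(os.path.join(outdir, files["orfs"]), orfs)
    write_utr_bed(os.path.join(outdir, files["utrs"]), utrs)
    write_vcf(
        os.path.join(outdir, files["variants"]),
        variants,
        {name: len(seq) for name, seq in genome.items()},
    )
    truth.to_csv(os.path.join(outdir, files["truth"]), sep="\t", index=False)
    rates.to_tsv(os.path.join(outdir, files["rates"]))
    write_csc_table(os.path.join(outdir, files["csc"]), csc)
    write_conservation_bedgraph(os.path.join(outdir, files["phylop"]), track)
    bb_truth.to_csv(os.path.join(outdir, files["biobank_truth"]), sep="\t", index=False)
    write_biobank(outdir, biobank)
    files.update(
        {
            "dosages": "dosages.tsv",
            "covariates": "covariates.tsv",
            "events": "events.tsv",
            "variant_annotations": "variant_annotations.tsv",
            "strata": "strata.tsv",
        }
    )
    return files


def annotate_stage(outdir: str, files: dict) -> pd.DataFrame:
    """Read inputs back from disk, QC-filter, and classify uORF variants."""
    genome = read_fasta(os.path.join(outdir, files["genome"]))
    orfs = read_orf_bed(os.path.join(outdir, files["orfs"]), genome)
    csc = read_csc_table(os.path.join(outdir, files["csc"]))
    variants, _ = read_variants_vcf(os.path.join(outdir, files["variants"]))
    variants = qc_filter(variants)
    for v in variants:
        v.context = context_from_genome(genome, v)
    calls = cq.classify_variants(orfs, variants, csc=csc, dedup=True)
    rows = []
    for c in calls:
        rows.append(
            {
                "chrom": c.variant.chrom,
                "pos": c.variant.pos,
                "ref": c.variant.ref,
                "alt": c.variant.alt,
                "orf_id": c.orf_id,
                "codon_index": c.codon_index,
                "codon_offset": c.codon_offset,
                "ref_codon": c.ref_codon,
                "alt_codon": c.alt_codon,
                "category": c.category,
                "new_stop": c.new_stop or "",
                "optimality": c.optimality,
                "singleton": c.variant.is_singleton,
                "context": c.variant.context,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(os.path.join(outdir, "consequence_calls.tsv"), sep="\t", index=False)
    return df


def _variant_classes(calls, variants_by_key):
    """Class label -> list of VariantRecord, from deduplicated calls."""
    classes: dict[str, list] = {}

    def add(label, call):
        v = variants_by_key[(call.variant.chrom, call.variant.pos, call.variant.alt)]
        classes.setdefault(label, []).append(v)

    for c in calls:
        add("all_uorf", c)
        if c.category == "stop_gain":
            add("utc_all", c)
            if c.new_stop == "UAA":
                add("utc_uaa", c)
        elif c.category == "stop_strengthen":
            add("stop_strengthen", c)
        elif c.category == "start_disrupt":
            add("start_disrupt", c)
        elif c.category == "start_maintain":
            add("start_maintain", c)
        elif c.category == "missense":
            add("uorf_missense", c)
        elif c.category == "synonymous":
            add("uorf_synonymous", c)
        if c.optimality == "increasing":
            add("optimality_increasing", c)
        elif c.optimality == "decreasing":
            add("optimality_decreasing", c)
    return classes


def maps_stage(config: PipelineConfig, outdir: str, files: dict, seed: int) -> dict:
    """Calibrate on the synthetic coding-synonymous class and score uORF classes."""
    genome = read_fasta(os.path.join(outdir, files["genome"]))
    orfs = read_orf_bed(os.path.join(outdir, files["orfs"]), genome)
    csc = read_csc_table(os.path.join(outdir, files["csc"]))
    rates = MutationRateTable.from_tsv(os.path.join(outdir, files["rates"]))
    variants, _ = read_variants_vcf(os.path.join(outdir, files["variants"]))
    variants = qc_filter(variants)
    for v in variants:
        v.context = context_from_genome(genome, v)
    variants = [v for v in variants if v.context is not None]

    neutral = [v for v in variants if v.chrom == "chr_cds"]
    model = MapsModel(neutral, rates).fit()

    calls = cq.classify_variants(orfs, variants, csc=csc, dedup=True)
    by_key = {(v.chrom, v.pos, v.alt): v for v in variants}
    classes = _variant_classes(calls, by_key)
    classes["coding_synonymous"] = neutral

    results = {}
    rng = np.random.default_rng(seed)
    for label in sorted(classes):
        members = classes[label]
        if not members:
            continue
        res = model.score_class(
            members,
            label=label,
            n_boot=config.maps_n_boot,
            percentiles=config.ci_percentiles,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        results[label] = res.to_dict()

    # headline contrasts: experimental class vs context-matched uORF controls
    pvals = {}
    pool = classes.get("all_uorf", [])
    for label in ("utc_all", "utc_uaa", "stop_strengthen", "start_disrupt"):
        members = classes.get(label, [])
        if not members or not pool:
            continue
        try:
            control = match_by_context(
                members, pool, seed=int(rng.integers(0, 2**31 - 1))
            )
        except KeyError:
            continue
        pvals[f"{label}_vs_context_matched"] = maps_pvalue(
            members,
            control,
            model,
            n_iter=config.maps_n_boot,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    out = {
        "calibration": {
            "intercept": model.intercept,
            "slope": model.slope,
            "n_contexts": len(model.model.training),
        },
        "classes": results,
        "p_values": pvals,
    }
    _write_json(os.path.join(outdir, "maps_results.json"), out)
    return out


def stop_usage_stage(config: PipelineConfig, outdir: str, files: dict, seed: int) -> dict:
    genome = read_fasta(os.path.join(outdir, files["genome"]))
    orfs = read_orf_bed(os.path.join(outdir, files["orfs"]), genome)
    utrs = read_utr_bed(os.path.join(outdir, files["utrs"]), genome)
    uorfs = [o for o in orfs if o.orf_class == "uORF"]
    n_iter = config.usage_n_iter
    rng = np.random.default_rng(seed)
    props, orf_draws = su.uorf_stop_frequencies(
        uorfs, n_iter=n_iter, seed=int(rng.integers(0, 2**31 - 1))
    )
    bg_all = su.background_stop_distribution(
        utrs, n_iter=n_iter, seed=int(rng.integers(0, 2**31 - 1))
    )
    bg_masked = su.background_stop_distribution(
        utrs,
        n_iter=n_iter,
        exclude_orf_overlap=True,
        orfs=uorfs,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    ci = {
        codon: list(np.percentile(orf_draws[:, k], (2.5, 97.5)))
        for k, codon in enumerate(su.STOP_ORDER)
    }
    out = {
        "uorf_proportions": dict(zip(su.STOP_ORDER, map(float, props))),
        "uorf_ci95": ci,
        "background_all_mean": dict(
            zip(su.STOP_ORDER, map(float, bg_all.mean(axis=0)))
        ),
        "background_masked_mean": dict(
            zip(su.STOP_ORDER, map(float, bg_masked.mean(axis=0)))
        ),
        "p_uaa_depletion_vs_all": su.usage_pvalue(orf_draws, bg_all, "UAA", "depletion"),
        "p_uga_enrichment_vs_all": su.usage_pvalue(orf_draws, bg_all, "UGA", "enrichment"),
        "p_uag_enrichment_vs_all": su.usage_pvalue(orf_draws, bg_all, "UAG", "enrichment"),
        "p_uaa_depletion_vs_masked": su.usage_pvalue(
            orf_draws, bg_masked, "UAA", "depletion"
        ),
        "n_iter": n_iter,
    }
    _write_json(os.path.join(outdir, "stop_usage_results.json"), out)
    return out


def conservation_stage(config: PipelineConfig, outdir: str, files: dict, seed: int) -> dict:
    from .genomic_model import read_conservation_bedgraph

    genome = read_fasta(os.path.join(outdir, files["genome"]))
    orfs = read_orf_bed(os.path.join(outdir, files["orfs"]), genome)
    utrs = read_utr_bed(os.path.join(outdir, files["utrs"]), genome)
    track = read_conservation_bedgraph(os.path.join(outdir, files["phylop"]))
    rng = np.random.default_rng(seed)
    n_iter = config.conservation_n_iter

    uorfs = [o for o in orfs if o.orf_class == "uORF"]
    stop_pos = [p for o in uorfs for p in cq.find_potential_stop_positions(o)]
    start_pos = [
        p for o in uorfs for p in cq.find_start_disrupting_positions(o, in_frame=True)
    ]
    orf_genomic = {
        (o.chrom, int(g)) for o in uorfs for g in o.genomic_positions()
    }
    utr_pool = [
        p
        for u in utrs
        for p in cq.find_utr_stop_creating_positions(
            u, exclude_orf_positions={g for c, g in orf_genomic if c == u.chrom}
        )
    ]

    out: dict = {"n_iter": n_iter}
    stop_prop = cons.conserved_proportion(
        stop_pos,
        track,
        n_boot=n_iter,
        seed=int(rng.integers(0, 2**31 - 1)),
        label="uorf_stop_creating",
    )
    start_prop = cons.conserved_proportion(
        start_pos,
        track,
        n_boot=n_iter,
        seed=int(rng.integers(0, 2**31 - 1)),
        label="uorf_start_disrupting",
    )
    out["uorf_stop_creating"] = stop_prop.to_dict()
    out["uorf_start_disrupting"] = start_prop.to_dict()
    try:
        matched = cons.match_by_cds_distance(
            stop_pos, utr_pool, seed=int(rng.integers(0, 2**31 - 1))
        )
        matched_prop = cons.conserved_proportion(
            matched,
            track,
            n_boot=n_iter,
            seed=int(rng.integers(0, 2**31 - 1)),
            label="distance_matched_controls",
        )
        out["distance_matched_controls"] = matched_prop.to_dict()
        out["p_stop_vs_matched"] = cons.proportion_pvalue(
            stop_pos,
            matched,
            track,
            n_iter=n_iter,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    except KeyError as exc:
        out["distance_matched_controls"] = f"unmatched: {exc}"
    _write_json(os.path.join(outdir, "conservation_results.json"), out)
    return out


def phewas_stage(config: PipelineConfig, outdir: str, files: dict) -> dict:
    from .genomic_model import read_biobank

    biobank = read_biobank(
        os.path.join(outdir, files["dosages"]),
        os.path.join(outdir, files["covariates"]),
        os.path.join(outdir, files["events"]),
        os.path.join(outdir, files["variant_annotations"]),
    )
    strata = pd.read_csv(
        os.path.join(outdir, files["strata"]), sep="\t", index_col=0
    )["ancestry"]
    truth = pd.read_csv(os.path.join(outdir, files["biobank_truth"]), sep="\t")
    test_variants = list(truth["variant"])
    codes = sorted(
        set(truth["phenotype"]) | set(
            c for c in biobank.events["code"].unique() if str(c).startswith("N")
        )
    )
    results = run_phewas(
        biobank.dosages[test_variants],
        biobank.covariates,
        biobank.events,
        codes,
        strata=strata,
    )
    results.to_csv(os.path.join(outdir, "phewas_results.tsv"), sep="\t", index=False)
    tested = results[results["tested"] == True]  # noqa: E712
    bonf, fdr_line = phewas_thresholds(len(test_variants), len(codes))

    # hypothesis-driven gene-burden follow-up on the target phenotypes
    burden_rows = []
    from .phewas import derive_case_control

    for row in truth.itertuples(index=False):
        burden = burden_collapse(
            row.gene, biobank.variant_annotations, biobank.dosages
        )
        status = derive_case_control(
            biobank.events, row.phenotype, biobank.dosages.index
        )
        if burden.sum() >= 5:
            res = logistic_assoc(
                burden,
                status,
                biobank.covariates,
                test_id=f"{row.gene}_burden",
                phenotype=row.phenotype,
            )
            burden_rows.append(res.to_dict())
    out = {
        "n_variants": len(test_variants),
        "n_phenotypes": len(codes),
        "bonferroni_p": bonf,
        "fdr_line_p": fdr_line,
        "n_tested": int(len(tested)),
        "associations": tested.to_dict(orient="records"),
        "burden": burden_rows,
    }
    _write_json(os.path.join(outdir, "phewas_summary.json"), out)
    return out


def run_pipeline(
    config: PipelineConfig, outdir: str, seed: int | None = None
) -> dict:
    """Run every stage, writing outputs and a manifest under ``outdir``.

    ``seed`` overrides the simulation seed and derives all stage seeds.
    Returns the manifest dict.
    """
    if seed is not None:
        config.simulation.seed = int(seed)
    base_seed = config.simulation.seed
    os.makedirs(outdir, exist_ok=True)
    logger.info("simulate stage")
    files = simulate_stage(config, outdir)
    logger.info("annotate stage")
    annotate_stage(outdir, files)
    logger.info("maps stage")
    maps_stage(config, outdir, files, seed=base_seed + 11)
    logger.info("stop-usage stage")
    stop_usage_stage(config, outdir, files, seed=base_seed + 12)
    logger.info("conservation stage")
    conservation_stage(config, outdir, files, seed=base_seed + 13)
    logger.info("phewas stage")
    phewas_stage(config, outdir, files)

    outputs = sorted(
        f
        for f in os.listdir(outdir)
        if os.path.isfile(os.path.join(outdir, f)) and f != "manifest.json"
    )
    manifest = {
        "config": dataclasses.asdict(config),
        "seed": base_seed,
        "stage_seeds": {
            "maps": base_seed + 11,
            "stop_usage": base_seed + 12,
            "conservation": base_seed + 13,
        },
        "files": {f: _sha256(os.path.join(outdir, f)) for f in outputs},
    }
    _write_json(os.path.join(outdir, "manifest.json"), manifest)
    return manifest


def rerun_from_manifest(manifest_path: str, outdir: str) -> tuple[dict, bool]:
    """Re-run the pipeline from a manifest; returns (new manifest, identical?)."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    raw = manifest["config"]
    sim_raw = dict(raw["simulation"])
    for key in ("utr_length_range", "uorf_codon_range", "rate_range"):
        sim_raw[key] = tuple(sim_raw[key])
    config = PipelineConfig(
        simulation=SimulationConfig(**sim_raw),
        maps_n_boot=raw["maps_n_boot"],
        usage_n_iter=raw["usage_n_iter"],
        conservation_n_iter=raw["conservation_n_iter"],
        ci_percentiles=tuple(raw["ci_percentiles"]),
    )
    new_manifest = run_pipeline(config, outdir, seed=manifest["seed"])
    identical = new_manifest["files"] == manifest["files"]
    return new_manifest, identical
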