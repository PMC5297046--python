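"""End-to-end orchestration: simulate -> call peaks -> assign -> test ->
allelic -> profiles -> report, from a single YAML-able config.

The pipeline runs on a synthetic dataset generated from the config's
``genome``/``effects`` blocks, or on user-supplied gene-level count tables
(``inputs`` block). In input mode the coverage-based stages (peak calling,
assignment, metagene profiles) are skipped with a warning, and the allelic
stage is skipped when no allelic count table is given.

ChIP testing order is configurable: ``test_level: peaks`` (default) tests
unified peak counts and maps significant peaks to genes through the
mark-specific assignment rules; ``test_level: genes`` tests gene-aggregated
counts directly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .allelic import (allelic_level_test, allelic_ratio_test, allelic_summary,
                      filter_sufficient)
from .assign import AssignmentRule, assign, gene_counts
from .differential import (ContrastSpec, build_mpv, classify_additivity,
                           compare_reciprocal, estimate_dispersion, nb_test,
                           normalize, size_factors)
from .intervals import CountMatrix
from .io import write_bed, write_tsv
from .peaks import PeakCallConfig, call_peaks, count_matrix, unify_peaks
from .profiles import (concordance, expression_correlation, heatmap_matrix,
                       metagene, stratify_te_lengths)
from .simulate import (HYBRIDS, MARKS, EffectModel, GenomeModel,
                       default_design, generate_counts, generate_genome)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 1
    outdir: str = "hybridhist_out"
    genome: dict = field(default_factory=dict)
    effects: dict = field(default_factory=dict)
    n_replicates: int = 2
    peak_calling: dict = field(default_factory=dict)  # per-mark overrides
    assignment: dict = field(default_factory=dict)  # per-mark overrides
    parental_fc: float = 1.5
    hybrid_fc: float = 1.25
    p_threshold: float = 0.05
    expr_fc: float = 1.3
    expr_p: float = 0.01
    min_snps: int = 2
    min_reads: int = 10
    test_level: str = "peaks"  # peaks | genes
    inputs: dict = field(default_factory=dict)  # optional real-data tables

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _stage(name):
    def deco(fn):
        def wrapper(self, *a, **kw):
            try:
                logger.info("stage %s", name)
                return fn(self, *a, **kw)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


class Pipeline:
    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "version": __version__,
            "seed": config.seed,
            "parameters": asdict(config),
            "stages": {},
        }
        self.data = None
        self.genes = []
        self.gene_counts: dict[str, CountMatrix] = {}
        self.peak_regions: dict = {}
        self.peak_counts: dict = {}
        self.assignments: dict = {}
        self.allelic_table = None
        self.diff: dict = {}
        self.report: dict = {}

    # -- stages ----------------------------------------------------------

    @_stage("simulate")
    def stage_simulate(self):
        cfg = self.config
        if cfg.inputs:
            self._load_inputs()
            return
        genome = generate_genome(GenomeModel(**cfg.genome), cfg.seed)
        design = default_design(cfg.n_replicates)
        self.data = generate_counts(genome, EffectModel(**cfg.effects), design, cfg.seed)
        self.genes = self.data.genome.genes
        for assay, cm in self.data.counts.items():
            write_tsv(cm.counts, self.outdir / f"counts_{assay}.tsv")
        write_tsv(self.data.genome.snps, self.outdir / "snps.tsv", index=False)
        write_tsv(self.data.truth.marks, self.outdir / "truth_marks.tsv", index=False)
        self.manifest["stages"]["simulate"] = {
            "n_genes": len(genome.genes),
            "n_tes": len(genome.tes),
            "n_snps": int(len(genome.snps)),
        }

    def _load_inputs(self):
        from .io import read_gff3, read_tsv

        inp = self.config.inputs
        for key in ("counts", "design"):
            if key not in inp:
                raise ValueError(f"inputs block is missing {key!r}")
        design = read_tsv(inp["design"]).set_index("sample_id")
        self.gene_counts = {
            assay: CountMatrix(read_tsv(path, index_col=0), design)
            for assay, path in inp["counts"].items()
        }
        self.genes = read_gff3(inp["genes"]) if "genes" in inp else []
        self.allelic_table = (
            read_tsv(inp["allelic"]) if "allelic" in inp else None
        )
        self.manifest["stages"]["simulate"] = {"mode": "inputs"}

    @_stage("callpeaks")
    def stage_peaks(self):
        if self.data is None:
            logger.warning("no coverage tracks in input mode; skipping peak calling")
            self.manifest["stages"]["callpeaks"] = {"skipped": True}
            return
        design = self.data.design
        self.peak_regions = {}
        self.peak_counts = {}
        self.assignments = {}
        for mark in MARKS:
            cfg = PeakCallConfig(mark=mark, **self.config.peak_calling.get(mark, {}))
            chip = design[design["assay"] == mark]
            peaksets = []
            coverages = {}
            for sid, row in chip.iterrows():
                treat = self.data.coverage.track(sid)
                ctrl_id = f"{row['genotype']}_input_r{row['replicate']}"
                ctrl = self.data.coverage.track(ctrl_id)
                peaksets.append(call_peaks(treat, ctrl, cfg, sample_id=sid))
                coverages[sid] = treat
            regions, table = unify_peaks(peaksets)
            self.peak_regions[mark] = regions
            write_bed(regions, self.outdir / f"peaks_{mark}.bed")
            pk_cm = count_matrix(regions, coverages, chip)
            self.peak_counts[mark] = pk_cm
            rule_over = self.config.assignment.get(mark, {})
            rule = (
                AssignmentRule(mark=mark, **rule_over)
                if rule_over
                else AssignmentRule.default_for(mark)
            )
            mapping = assign(regions, self.genes, rule)
            self.assignments[mark] = mapping
            self.gene_counts[mark] = gene_counts(mapping, pk_cm)
            write_tsv(mapping, self.outdir / f"assignment_{mark}.tsv", index=False)
            self.manifest["stages"].setdefault("callpeaks", {})[mark] = {
                "n_peaks": len(regions),
                "n_target_genes": int(mapping["gene_id"].nunique()),
            }
        self.gene_counts["RNA"] = self.data.counts["RNA"]

    @_stage("diff")
    def stage_diff(self):
        if self.data is not None and self.config.test_level == "genes":
            # bypass peak aggregation: test the generator's gene-level counts
            self.gene_counts = dict(self.data.counts)
        results = {}
        for assay, cm in self.gene_counts.items():
            if assay == "RNA":
                fc_par, fc_hyb, p = self.config.expr_fc, self.config.expr_fc, self.config.expr_p
            else:
                fc_par, fc_hyb, p = (
                    self.config.parental_fc, self.config.hybrid_fc, self.config.p_threshold,
                )
            use_peaks = (
                assay != "RNA"
                and self.config.test_level == "peaks"
                and assay in self.peak_counts
            )
            source = self.peak_counts[assay] if use_peaks else cm
            res = differential_suite(
                source.counts, source.samples,
                fc_parental=fc_par, fc_hybrid=fc_hyb, p_threshold=p,
            )
            if use_peaks:
                res = map_peak_results_to_genes(res, self.assignments[assay])
            results[assay] = res
            for name, df in res["contrasts"].items():
                write_tsv(df, self.outdir / f"diff_{assay}_{name}.tsv")
        self.diff = results
        self.manifest["stages"]["diff"] = {
            assay: {name: int(df["is_dmg"].sum()) for name, df in r["contrasts"].items()}
            for assay, r in results.items()
        }

    @_stage("allelic")
    def stage_allelic(self):
        table = (
            self.data.allelic if self.data is not None
            else getattr(self, "allelic_table", None)
        )
        if table is None:
            logger.warning("no SNP/allelic table provided; skipping allelic stage")
            self.manifest["stages"]["allelic"] = {"skipped": True}
            return
        out = {}
        for mark in MARKS:
            if mark not in self.gene_counts:
                continue
            sub = table[table["mark"] == mark] if "mark" in table else table
            cm = self.gene_counts[mark]
            sf = size_factors(cm.counts)
            norm = normalize(cm.counts, sf)
            p1 = norm[cm.group_columns("P1")]
            p2 = norm[cm.group_columns("P2")]
            parent_levels = pd.DataFrame(
                {"P1": p1.mean(axis=1), "P2": p2.mean(axis=1)}
            )
            disp = estimate_dispersion(
                norm, [cm.group_columns(g) for g in ("P1", "P2") + HYBRIDS]
            )["alpha"]
            passing = filter_sufficient(sub, self.config.min_snps, self.config.min_reads)
            level_tests = {}
            per_cross = {}
            for cross in HYBRIDS:
                cross_samples = cm.samples.index[cm.samples["genotype"] == cross]
                csub = sub[sub["sample_id"].isin(cross_samples)]
                ratio = allelic_ratio_test(csub, parent_levels, genes=passing)
                level = allelic_level_test(
                    csub, {"P1": p1, "P2": p2}, disp, passing
                )
                level_tests[cross] = level
                per_cross[cross] = {
                    "ratio": ratio,
                    "n_tested": int(ratio["testable"].sum()),
                    "n_ratio_significant": int(
                        ((ratio["pval"] <= 0.05) & ratio["testable"]).sum()
                    ),
                }
                write_tsv(ratio, self.outdir / f"allelic_ratio_{mark}_{cross}.tsv")
            summary = allelic_summary(level_tests)
            write_tsv(summary, self.outdir / f"allelic_summary_{mark}.tsv")
            out[mark] = {
                "n_sufficient": len(passing),
                "per_cross": per_cross,
                "summary": summary,
            }
        self.allelic_results = out
        self.manifest["stages"]["allelic"] = {
            mark: {
                "n_sufficient": v["n_sufficient"],
                **{
                    c: {k: vv for k, vv in d.items() if k != "ratio"}
                    for c, d in v["per_cross"].items()
                },
            }
            for mark, v in out.items()
        }

    @_stage("profiles")
    def stage_profiles(self):
        if self.data is None:
            logger.warning("no coverage in input mode; skipping metagene profiles")
            self.manifest["stages"]["profiles"] = {"skipped": True}
            self.concordance_tables = {}
            return
        genes = [g for g in self.genes if g.feature_class == "protein_coding"]
        profs = {}
        for mark in MARKS:
            track = self.data.coverage.track(f"P1_{mark}_r1")
            profs[mark] = metagene(track, genes, mark=mark, sample="P1_r1")
        long_te, short_te = stratify_te_lengths(self.data.genome.tes)
        k9_track = self.data.coverage.track("P1_K9me2_r1")
        te_profiles = {
            "long": metagene(k9_track, long_te, mark="K9me2", sample="long_TE"),
            "short": metagene(k9_track, short_te, mark="K9me2", sample="short_TE"),
        }
        self.metagene_profiles = profs
        self.te_profiles = te_profiles

        # gene-level signals and expression correlation
        rna = self.gene_counts["RNA"]
        expr = normalize(rna.counts).mean(axis=1)
        corr = {}
        signals = {}
        for mark in MARKS:
            cm = self.gene_counts[mark]
            if not len(cm.counts):
                continue
            lvl = normalize(cm.counts).mean(axis=1)
            signals[mark] = lvl
            corr[mark] = expression_correlation(lvl, expr)
        self.heatmap = heatmap_matrix(
            pd.DataFrame(signals).fillna(0.0), order_by="K4me3"
        )
        write_tsv(self.heatmap, self.outdir / "heatmap_matrix.tsv")
        self.expression_corr = corr

        # concordance per mark, Ler x C24 -style cross first
        conc_tables = {}
        conc_counts = {}
        for mark in MARKS:
            if mark not in self.diff:
                continue
            tables = {}
            for cross in HYBRIDS:
                tab, cnt = concordance(
                    self.diff[mark]["contrasts"]["parental"],
                    self.diff["RNA"]["contrasts"]["parental"],
                    self.diff[mark]["contrasts"][f"{cross}_vs_MPV"],
                    self.diff["RNA"]["contrasts"][f"{cross}_vs_MPV"],
                    mark,
                    expr_fc=self.config.expr_fc,
                    expr_p=self.config.expr_p,
                )
                tables[cross] = tab
                conc_counts[f"{mark}_{cross}"] = cnt
                write_tsv(tab, self.outdir / f"concordance_{mark}_{cross}.tsv")
            conc_tables[mark] = tables
        self.concordance_tables = conc_tables
        self.manifest["stages"]["profiles"] = {
            "expression_spearman": {
                m: (None if c["spearman_rho"] is None else round(c["spearman_rho"], 4))
                for m, c in corr.items()
            },
            "concordance": conc_counts,
        }

    @_stage("report")
    def stage_report(self):
        report = {"dmg_counts": {}, "reciprocal_fisher": {}}
        for assay, res in self.diff.items():
            report["dmg_counts"][assay] = {
                name: int(df["is_dmg"].sum()) for name, df in res["contrasts"].items()
            }
            if assay == "RNA":
                continue
            a = res["contrasts"]["P1xP2_vs_MPV"]
            b = res["contrasts"]["P2xP1_vs_MPV"]
            report["reciprocal_fisher"][assay] = compare_reciprocal(
                (int(a["is_dmg"].sum()), len(a)), (int(b["is_dmg"].sum()), len(b))
            )
        report["additivity"] = {
            assay: res["additivity"]["P1xP2"]["additivity"].value_counts().to_dict()
            for assay, res in self.diff.items()
            if "additivity" in res and "P1xP2" in res["additivity"]
        }
        report["concordance"] = {
            f"{mark}_{cross}": int(tab["hybrid_concordant"].sum())
            for mark, tables in getattr(self, "concordance_tables", {}).items()
            for cross, tab in tables.items()
        }
        report["allelic"] = {
            mark: {
                "n_sufficient": v["n_sufficient"],
                "classification_counts": v["summary"]["classification"]
                .value_counts()
                .to_dict(),
            }
            for mark, v in getattr(self, "allelic_results", {}).items()
        }
        self.report = report
        self.manifest["stages"]["report"] = report
        cfg_text = json.dumps(self.manifest["parameters"], sort_keys=True)
        self.manifest["config_sha256"] = hashlib.sha256(cfg_text.encode()).hexdigest()
        with open(self.outdir / "manifest.json", "w") as fh:
            json.dump(_jsonable(self.manifest), fh, indent=2, sort_keys=True)

    def run(self) -> dict:
        self.stage_simulate()
        self.stage_peaks()
        self.stage_diff()
        self.stage_allelic()
        self.stage_profiles()
        self.stage_report()
        return self.report


# -- differential helpers used by both the pipeline and callers ------------


def differential_suite(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    fc_parental: float = 1.5,
    fc_hybrid: float = 1.25,
    p_threshold: float = 0.05,
) -> dict:
    """Parental and hybrid-vs-MPV contrasts for one count matrix.

    Returns {'size_factors', 'dispersions', 'contrasts': {...}, 'additivity'}.
    """
    def cols(genotype):
        sel = samples.index[samples["genotype"] == genotype]
        return sorted(sel, key=lambda s: samples.loc[s, "replicate"])

    if not len(counts):
        raise ValueError("empty count matrix")
    sf = size_factors(counts)
    norm = normalize(counts, sf)
    groups = [cols(g) for g in ("P1", "P2") + HYBRIDS if cols(g)]
    disp = estimate_dispersion(norm, groups)

    p1, p2 = norm[cols("P1")], norm[cols("P2")]
    contrasts = {}
    parental_spec = ContrastSpec(
        "parent_vs_parent", fc_threshold=fc_parental, p_threshold=p_threshold
    )
    contrasts["parental"] = nb_test(p1, p2, disp["alpha"], parental_spec)

    mpv = build_mpv(norm, cols("P1"), cols("P2"))
    additivity = {}
    for cross in HYBRIDS:
        if not cols(cross):
            continue
        hyb = norm[cols(cross)]
        spec = ContrastSpec(
            "hybrid_vs_MPV", fc_threshold=fc_hybrid, p_threshold=p_threshold
        )
        res = nb_test(hyb, mpv, disp["alpha"], spec)
        contrasts[f"{cross}_vs_MPV"] = res
        additivity[cross] = classify_additivity(hyb, p1, p2, contrasts["parental"], res)
    return {
        "size_factors": sf,
        "dispersions": disp,
        "normalized": norm,
        "contrasts": contrasts,
        "additivity": additivity,
    }


def map_peak_results_to_genes(res: dict, mapping: pd.DataFrame) -> dict:
    """Project peak-level differential results onto genes.

    A gene inherits, per contrast, its most-changed qualifying peak
    (largest |log2fc| among its peaks); the gene is a DMG when any of its
    peaks is. The peak-level tables are kept under 'peak_contrasts'.
    """
    out = dict(res)
    out["peak_contrasts"] = res["contrasts"]
    gene_contrasts = {}
    peak_ids = None
    for name, df in res["contrasts"].items():
        peak_ids = df.index
        rows = []
        for gene_id, grp in mapping.groupby("gene_id"):
            sub = df.iloc[sorted(grp["peak_index"].unique())]
            best = sub.loc[sub["log2fc"].abs().idxmax()]
            rows.append(
                (gene_id, best["baseMean_A"], best["baseMean_B"], best["log2fc"],
                 sub["pval"].min(), bool(sub["is_dmg"].any()), best["direction"])
            )
        gene_contrasts[name] = pd.DataFrame(
            rows,
            columns=["gene_id", "baseMean_A", "baseMean_B", "log2fc", "pval",
                     "is_dmg", "direction"],
        ).set_index("gene_id")
    out["contrasts"] = gene_contrasts
    # additivity was computed at peak level; recompute gene-level membership
    out["additivity"] = {
        cross: tab for cross, tab in res.get("additivity", {}).items()
    }
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return None
    return obj
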