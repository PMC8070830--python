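"""End-to-end orchestration: simulate -> catalog -> de -> mirna -> targets
-> enrich -> network, with a machine-readable run report.

Stages communicate through fixed-name files in the run directory, so any
stage can be re-run from the cached outputs of the previous ones. All
randomness flows through the single configured seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import catalog as cat
from . import core_io as io
from . import diffexpr as de
from . import interactions as ix
from . import mirna_links as ml
from . import synthetic_data as sd

__all__ = ["PipelineError", "RunReport", "default_config", "run_pipeline", "STAGES"]

STAGES = ["simulate", "catalog", "de", "mirna", "targets", "enrich", "network"]


class PipelineError(RuntimeError):
    pass


def default_config() -> dict:
    return {
        "seed": 42,
        "outdir": "felnc_run",
        "simulate": True,
        "sim": {},
        "inputs": {},
        "thresholds": {
            "min_length": cat.MIN_LNCRNA_LENGTH,
            "max_coding_score": 0.0,
            "cis_proximity": cat.CIS_PROXIMITY_NT,
            "min_abs_log2fc": 1.0,
            "min_fpkm": 2.0,
            "min_probability": 0.8,
            "max_expectation": ml.DEFAULT_MAX_EXPECTATION,
            "cis_window": ix.CIS_WINDOW_NT,
            "cis_ndg_max": ix.CIS_NDG_MAX,
            "trans_ndg_max": ix.TRANS_NDG_MAX,
            "go_p_max": ix.GO_P_MAX,
        },
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _validate_config(cfg: dict) -> None:
    th = cfg["thresholds"]
    if not (0.0 <= th["min_probability"] <= 1.0):
        raise PipelineError("min_probability must lie in [0, 1]")
    if th["min_length"] < 1:
        raise PipelineError("min_length must be positive")
    if th["max_expectation"] < 0:
        raise PipelineError("max_expectation must be non-negative")
    if th["cis_ndg_max"] > 0 or th["trans_ndg_max"] > 0:
        raise PipelineError("ndG thresholds must be <= 0")
    if not cfg.get("simulate", False):
        required = ["gtf", "genome", "counts", "design"]
        missing = [k for k in required if k not in cfg.get("inputs", {})]
        if missing:
            raise PipelineError(f"missing input path(s): {missing}")


@dataclass
class RunReport:
    seed: int
    thresholds: dict
    stage_seconds: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    failed_stage: str | None = None

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def _rows(path: Path) -> int:
    """Data rows of a headered TSV."""
    with open(path) as fh:
        return max(0, sum(1 for _ in fh) - 1)


class _Ctx:
    """Lazily loaded shared state between stages."""

    def __init__(self, cfg: dict, outdir: Path):
        self.cfg = cfg
        self.outdir = outdir
        self._cache: dict = {}

    def _input(self, key: str) -> Path:
        if self.cfg.get("simulate", False):
            return self.outdir / "inputs" / {
                "gtf": "transcripts.gtf",
                "genome": "genome.fa",
                "counts": "counts.tsv",
                "design": "design.tsv",
                "mirna": "mirna.tsv",
                "mature_mirna": "mature_mirna.txt",
                "go_annotation": "go_annotation.tsv",
                "go_terms": "go_terms.tsv",
                "fe_genes": "fe_genes.txt",
            }[key]
        return Path(self.cfg["inputs"][key])

    def transcripts(self) -> list[io.TranscriptModel]:
        if "transcripts" not in self._cache:
            self._cache["transcripts"] = io.read_gtf(self._input("gtf"))
        return self._cache["transcripts"]

    def genome(self) -> dict[str, str]:
        if "genome" not in self._cache:
            self._cache["genome"] = io.read_fasta(self._input("genome"))
        return self._cache["genome"]

    def sequences(self) -> dict[str, str]:
        if "sequences" not in self._cache:
            g = self.genome()
            self._cache["sequences"] = {
                t.transcript_id: io.extract_transcript_sequence(t, g)
                for t in self.transcripts()
            }
        return self._cache["sequences"]

    def catalog_table(self) -> pd.DataFrame:
        if "catalog" not in self._cache:
            path = self.outdir / "catalog.tsv"
            if not path.exists():
                raise PipelineError("catalog stage has not been run")
            self._cache["catalog"] = pd.read_csv(
                path, sep="\t", index_col="transcript_id"
            )
        return self._cache["catalog"]

    def de_tables(self) -> dict[str, pd.DataFrame]:
        if "de" not in self._cache:
            tables = {}
            for tissue in ("shoot", "root"):
                path = self.outdir / f"de_{tissue}.tsv"
                if not path.exists():
                    raise PipelineError("de stage has not been run")
                tables[tissue] = pd.read_csv(path, sep="\t", index_col="transcript_id")
            self._cache["de"] = tables
        return self._cache["de"]

    def de_ids(self, biotype: str) -> list[str]:
        """Transcripts of a biotype called up/down in at least one tissue."""
        catalog = self.catalog_table()
        wanted = set(catalog.index[catalog["biotype"] == biotype])
        out: set[str] = set()
        for df in self.de_tables().values():
            sig = df.index[df["status"].isin(["up", "down"])]
            out |= set(sig) & wanted
        return sorted(out)


def _stage_simulate(ctx: _Ctx, report: RunReport) -> None:
    sim_cfg = sd.SimConfig(**{"seed": ctx.cfg["seed"], **ctx.cfg.get("sim", {})})
    study = sd.simulate_study(sim_cfg)
    sd.write_study(study, ctx.outdir / "inputs")
    report.counts["simulated_transcripts"] = len(study.transcripts)


def _stage_catalog(ctx: _Ctx, report: RunReport) -> None:
    th = ctx.cfg["thresholds"]
    transcripts = ctx.transcripts()
    genome = ctx.genome()
    result = cat.identify_lncrnas(transcripts, genome, min_length=th["min_length"])
    index = cat.CodingIndex(result.mrnas)
    rows = []
    gtf_attrs = {}
    for t in result.lncrnas:
        label = cat.classify_lncrna(t, index, max_gap=th["cis_proximity"])
        s = result.scores[t.transcript_id]
        rows.append(
            {"transcript_id": t.transcript_id, "biotype": "lncRNA",
             "class": label.label, "evidence": label.evidence or "",
             "partner_gene_id": label.partner_gene_id or "",
             "distance": label.distance, "overlap_nt": label.overlap_nt,
             "score": round(s.score, 6), "orf_length": s.orf_length,
             "orf_coverage": round(s.orf_coverage, 6),
             "orf_integrity": s.orf_integrity}
        )
        gtf_attrs[t.transcript_id] = {"lncRNA_class": label.label}
    for t in result.mrnas:
        s = result.scores[t.transcript_id]
        rows.append(
            {"transcript_id": t.transcript_id, "biotype": "coding", "class": "",
             "evidence": "", "partner_gene_id": "", "distance": 0,
             "overlap_nt": 0, "score": round(s.score, 6),
             "orf_length": s.orf_length,
             "orf_coverage": round(s.orf_coverage, 6),
             "orf_integrity": s.orf_integrity}
        )
    df = pd.DataFrame(rows).set_index("transcript_id").sort_index()
    df.to_csv(ctx.outdir / "catalog.tsv", sep="\t")
    io.write_gtf(result.lncrnas, ctx.outdir / "lncrnas.gtf", extra_attrs=gtf_attrs)
    report.counts["n_lncrna"] = len(result.lncrnas)
    report.counts["n_mrna"] = len(result.mrnas)
    for klass in ("intergenic", "cis_sense", "antisense"):
        report.counts[f"n_lncrna_{klass}"] = int((df["class"] == klass).sum())


def _stage_de(ctx: _Ctx, report: RunReport) -> None:
    th = ctx.cfg["thresholds"]
    samples = io.read_design_tsv(ctx._input("design"))
    counts = io.read_counts_tsv(ctx._input("counts"), samples)
    catalog = ctx.catalog_table()
    keep = [tid for tid in counts.values.index if tid in catalog.index]
    counts = io.ExpressionMatrix(counts.values.loc[keep], samples, "count")
    fpkm = io.compute_fpkm(counts, ctx.transcripts())
    thresholds = de.DEThresholds(
        th["min_abs_log2fc"], th["min_fpkm"], th["min_probability"]
    )
    tables = {}
    for tissue in ("shoot", "root"):
        stats = de.noiseq_probability(fpkm, tissue)
        called = de.call_de(stats, thresholds)
        called.insert(0, "biotype", catalog["biotype"].reindex(called.index))
        called.to_csv(ctx.outdir / f"de_{tissue}.tsv", sep="\t", float_format="%.6g")
        tables[tissue] = called
        for status in ("up", "down"):
            for biotype in ("lncRNA", "coding"):
                n = int(
                    ((called["status"] == status) & (called["biotype"] == biotype)).sum()
                )
                report.counts[f"n_de_{biotype}_{tissue}_{status}"] = n
    classes = de.classify_expression(tables["shoot"], tables["root"])
    classes.insert(0, "biotype", catalog["biotype"].reindex(classes.index))
    classes.sort_index().to_csv(ctx.outdir / "classes.tsv", sep="\t")
    summary = de.de_summary(tables, classes)
    with open(ctx.outdir / "de_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    report.counts["n_de_rows_shoot"] = len(tables["shoot"])
    report.counts["n_de_rows_root"] = len(tables["root"])
    for cls, n in summary["class_sizes"].items():
        report.counts[f"class_{cls}"] = n


def _read_mature_mirnas(path: Path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) == 2:
                out[parts[0]] = parts[1]
    return out


def _stage_mirna(ctx: _Ctx, report: RunReport) -> None:
    th = ctx.cfg["thresholds"]
    seqs = ctx.sequences()
    models = {t.transcript_id: t for t in ctx.transcripts()}
    de_lnc = ctx.de_ids("lncRNA")
    de_mrna = ctx.de_ids("coding")
    pres = ml.read_mirna_tsv(ctx._input("mirna"))
    matures = _read_mature_mirnas(ctx._input("mature_mirna"))

    pre_pairs = ml.find_precursor_lncrnas([models[i] for i in de_lnc], pres)
    with open(ctx.outdir / "precursors.tsv", "w") as fh:
        fh.write("lncrna_id\tmirna_id\n")
        for lnc_id, mid in sorted(pre_pairs):
            fh.write(f"{lnc_id}\t{mid}\n")

    target_hits: list[ml.MirnaTargetHit] = []
    etm_hits: list[ml.EtmHit] = []
    mrna_seqs = {i: seqs[i] for i in de_mrna}
    lnc_seqs = {i: seqs[i] for i in de_lnc}
    for mid, mature in sorted(matures.items()):
        target_hits += ml.predict_mirna_targets(
            mature, mrna_seqs, mirna_id=mid, e_max=th["max_expectation"]
        )
        etm_hits += ml.find_etm(mature, lnc_seqs, mirna_id=mid)
    with open(ctx.outdir / "target_hits.tsv", "w") as fh:
        fh.write(
            "mirna_id\ttarget_id\ttarget_start\texpectation\tn_mismatch\tn_gu\tinhibition\n"
        )
        for h in target_hits:
            fh.write(
                f"{h.mirna_id}\t{h.target_id}\t{h.target_start}\t{h.expectation:g}\t"
                f"{h.n_mismatch}\t{h.n_gu}\t{h.inhibition}\n"
            )
    with open(ctx.outdir / "etm_hits.tsv", "w") as fh:
        fh.write("mirna_id\tlncrna_id\tsite_start\tbulge_len\tn_mismatch\tn_gu\n")
        for h in etm_hits:
            fh.write(
                f"{h.mirna_id}\t{h.lncrna_id}\t{h.site_start}\t{h.bulge_len}\t"
                f"{h.n_mismatch}\t{h.n_gu}\n"
            )
    with open(ctx.outdir / "alignments.txt", "w") as fh:
        for h in target_hits:
            fh.write(f"# {h.mirna_id} -> {h.target_id} @{h.target_start} "
                     f"(expectation {h.expectation:g}, {h.inhibition})\n")
            fh.write(h.alignment + "\n\n")
        for h in etm_hits:
            fh.write(f"# eTM {h.mirna_id} ~ {h.lncrna_id} @{h.site_start}\n")
            fh.write(h.alignment + "\n\n")
    report.counts["n_precursor_pairs"] = len(pre_pairs)
    report.counts["n_target_hits"] = len(target_hits)
    report.counts["n_etm_hits"] = len(etm_hits)


def _stage_targets(ctx: _Ctx, report: RunReport) -> None:
    th = ctx.cfg["thresholds"]
    catalog = ctx.catalog_table()
    seqs = ctx.sequences()
    models = ctx.transcripts()
    lncs = [m for m in models if m.transcript_id in catalog.index
            and catalog.loc[m.transcript_id, "biotype"] == "lncRNA"]
    genes = [m for m in models if m.transcript_id in catalog.index
             and catalog.loc[m.transcript_id, "biotype"] == "coding"]
    de_lnc = ctx.de_ids("lncRNA")
    de_mrna = ctx.de_ids("coding")
    cis_edges = ix.find_cis_targets(
        lncs, seqs, genes, seqs, de_lnc,
        window=th["cis_window"], ndg_max=th["cis_ndg_max"],
    )
    trans_edges = ix.find_trans_targets(
        {i: seqs[i] for i in de_lnc},
        {i: seqs[i] for i in de_mrna},
        ndg_max=th["trans_ndg_max"],
    )
    gene_of = {m.transcript_id: m.gene_id for m in models}
    with open(ctx.outdir / "cis_edges.tsv", "w") as fh:
        fh.write("lncrna_id\tgene_id\tdistance\tndG\n")
        for e in sorted(cis_edges, key=lambda e: (e.lncrna_id, e.gene_id)):
            fh.write(f"{e.lncrna_id}\t{e.gene_id}\t{e.distance}\t{e.ndG:.6g}\n")
    with open(ctx.outdir / "trans_edges.tsv", "w") as fh:
        fh.write("lncrna_id\tgene_id\tndG\n")
        for e in sorted(trans_edges, key=lambda e: (e.lncrna_id, e.gene_id)):
            gid = gene_of.get(e.gene_id, e.gene_id)
            fh.write(f"{e.lncrna_id}\t{gid}\t{e.ndG:.6g}\n")
    report.counts["n_cis_edges"] = len(cis_edges)
    report.counts["n_trans_edges"] = len(trans_edges)


def _read_go_inputs(ctx: _Ctx):
    annot: dict[str, list[str]] = {}
    df = pd.read_csv(ctx._input("go_annotation"), sep="\t")
    for r in df.itertuples():
        annot.setdefault(r.gene_id, []).append(r.term_id)
    tdf = pd.read_csv(ctx._input("go_terms"), sep="\t")
    terms = {r.term_id: (r.name, r.namespace) for r in tdf.itertuples()}
    return annot, terms


def _stage_enrich(ctx: _Ctx, report: RunReport) -> None:
    th = ctx.cfg["thresholds"]
    trans = pd.read_csv(ctx.outdir / "trans_edges.tsv", sep="\t")
    selected = set(trans["gene_id"])
    models = ctx.transcripts()
    catalog = ctx.catalog_table()
    universe = {
        m.gene_id for m in models
        if m.transcript_id in catalog.index
        and catalog.loc[m.transcript_id, "biotype"] == "coding"
    }
    annot, terms = _read_go_inputs(ctx)
    results = ix.go_enrichment(
        selected & universe, universe, annot, terms, p_max=th["go_p_max"]
    )
    with open(ctx.outdir / "go_enrichment.tsv", "w") as fh:
        fh.write("term_id\tname\tnamespace\tk\tK\tn\tN\tp\n")
        for r in results:
            fh.write(
                f"{r.term_id}\t{r.term_name}\t{r.namespace}\t{r.k}\t{r.K}\t"
                f"{r.n}\t{r.N}\t{r.p:.6g}\n"
            )
    report.counts["n_enriched_terms"] = len(results)


def _stage_network(ctx: _Ctx, report: RunReport) -> None:
    trans = pd.read_csv(ctx.outdir / "trans_edges.tsv", sep="\t")
    edges = [
        ix.TargetEdge(r.lncrna_id, r.gene_id, "trans", None, r.ndG)
        for r in trans.itertuples()
    ]
    fe_genes = [
        line.strip() for line in open(ctx._input("fe_genes")) if line.strip()
    ]
    direction: dict[str, str] = {}
    models = {t.transcript_id: t for t in ctx.transcripts()}
    gene_tids = {t.gene_id: tid for tid, t in models.items()}
    for tissue, df in ctx.de_tables().items():
        for tid, status in df["status"].items():
            if status in ("up", "down"):
                direction.setdefault(tid, status)
                gid = models[tid].gene_id if tid in models else tid
                direction.setdefault(gid, status)
    g = ix.build_network(edges, direction, fe_genes, outdir=ctx.outdir)
    report.counts["n_network_nodes"] = g.number_of_nodes()
    report.counts["n_network_edges"] = g.number_of_edges()
    report.counts["n_hub_lncrnas"] = sum(
        1 for _, d in g.nodes(data=True) if d.get("hub")
    )


_STAGE_FN = {
    "simulate": _stage_simulate,
    "catalog": _stage_catalog,
    "de": _stage_de,
    "mirna": _stage_mirna,
    "targets": _stage_targets,
    "enrich": _stage_enrich,
    "network": _stage_network,
}


def run_pipeline(config: dict | None = None, stages: list[str] | None = None) -> RunReport:
    """Execute the requested stages (all of them by default) and write
    ``report.json`` into the run directory."""
    cfg = _merge(default_config(), config or {})
    _validate_config(cfg)
    wanted = stages or STAGES
    unknown = [s for s in wanted if s not in STAGES]
    if unknown:
        raise PipelineError(f"unknown stage(s): {unknown}")
    if not cfg.get("simulate", False):
        wanted = [s for s in wanted if s != "simulate"]
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=cfg["seed"], thresholds=cfg["thresholds"])
    ctx = _Ctx(cfg, outdir)
    for stage in STAGES:
        if stage not in wanted:
            continue
        t0 = time.perf_counter()
        try:
            _STAGE_FN[stage](ctx, report)
        except Exception:
            report.failed_stage = stage
            report.write(outdir / "report.json")
            raise
        report.stage_seconds[stage] = round(time.perf_counter() - t0, 3)
    for key in ("gtf", "genome", "counts", "design"):
        try:
            path = ctx._input(key)
            if path.exists():
                report.input_digests[key] = _digest(path)
        except KeyError:
            pass
    report.write(outdir / "report.json")
    return report
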