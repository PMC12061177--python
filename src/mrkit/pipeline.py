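"""End-to-end bidirectional MR analysis from a single configuration.

Stage order per pair: exposure p-value threshold → LD clumping (skipped with
an audit note when no LD table is supplied, e.g. for generated independent
instruments) → weak-instrument (F) filter → outcome-association filter →
harmonization (palindrome removal) → Steiger directionality filter →
confounder exclusion → estimation → sensitivity battery.  If MR-PRESSO or
Radial MR flags outliers, they are removed and estimation + sensitivity are
re-run exactly once; both passes are retained.  Every input SNP appears
exactly once in the audit trail: as a surviving instrument or as one
exclusion-log entry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .estimators import cml_ma, ivw, mr_egger, wald_ratio, weighted_median
from .exceptions import EmptyInstrumentError, InsufficientInstrumentsError
from .harmonize import Exclusion, HarmonizedSet, harmonize_set
from .instruments import (InstrumentCriteria, LDInfo, filter_by_exposure_p,
                          instrument_strength, ld_clump, steiger_filter)
from .report import PairResult, assemble_report
from .sensitivity import sensitivity_report
from .sumstats_io import SummaryStats, read_sumstats, write_table

__all__ = ["AnalysisConfig", "FileSpec", "run_pair", "run_bidirectional",
           "load_config"]

DEFAULT_METHODS = ("ivw", "egger", "wmedian", "cml")


@dataclass(frozen=True)
class FileSpec:
    """One summary-statistic input: path, label and optional column map."""

    path: str
    label: str
    column_map: Mapping[str, str] | None = None
    delimiter: str | None = None

    def load(self) -> SummaryStats:
        return read_sumstats(self.path, column_map=self.column_map,
                             trait_label=self.label, delimiter=self.delimiter)


@dataclass
class AnalysisConfig:
    """Configuration of a full bidirectional analysis.

    The forward direction treats ``exposure`` as the exposure against every
    entry of ``outcomes``; the reverse direction swaps roles, conventionally
    with a relaxed exposure p-value threshold (5e-6 vs 5e-8) because few
    SNPs reach genome-wide significance in the smaller outcome GWAS.
    """

    exposure: FileSpec
    outcomes: Sequence[FileSpec]
    forward_criteria: InstrumentCriteria = field(default_factory=InstrumentCriteria)
    reverse_criteria: InstrumentCriteria = field(
        default_factory=lambda: InstrumentCriteria(p_exposure_max=5e-6))
    methods: Sequence[str] = DEFAULT_METHODS
    seed: int = 0
    n_boot: int = 1000
    presso_nsim: int = 1000
    ld: LDInfo | None = None
    outdir: str | None = None


def _cfg_criteria(section: Mapping, base: InstrumentCriteria) -> InstrumentCriteria:
    kwargs = {k: section[k] for k in
              ("p_exposure_max", "clump_r2_max", "clump_window_kb", "f_min",
               "p_outcome_min") if k in section}
    if "exclusion_list" in section:
        excl = section["exclusion_list"]
        if isinstance(excl, str):
            with open(excl) as fh:
                excl = [line.strip() for line in fh if line.strip()]
        kwargs["exclusion_list"] = frozenset(excl)
    defaults = {"p_exposure_max": base.p_exposure_max}
    defaults.update(kwargs)
    return InstrumentCriteria(**defaults)


def load_config(path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML file.

    Expected layout::

        exposure: {path: ..., label: ..., column_map: {...}}
        outcomes:
          - {path: ..., label: ...}
        forward: {p_exposure_max: 5.0e-8, f_min: 10, ...}
        reverse: {p_exposure_max: 5.0e-6, ...}
        methods: [ivw, egger, wmedian, cml]
        seed: 17
        ld: {positions: pos.tsv, pairs: ld.tsv}   # optional
        outdir: results/
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)

    def spec(d):
        return FileSpec(d["path"], d.get("label", d["path"]),
                        d.get("column_map"), d.get("delimiter"))

    ld = None
    if "ld" in raw and raw["ld"]:
        pos = pd.read_csv(raw["ld"]["positions"], sep="\t")
        pairs = (pd.read_csv(raw["ld"]["pairs"], sep="\t")
                 if raw["ld"].get("pairs") else None)
        matrix = (pd.read_csv(raw["ld"]["matrix"], sep="\t", index_col=0)
                  if raw["ld"].get("matrix") else None)
        ld = LDInfo.from_tables(pos, pairs=pairs, matrix=matrix)

    return AnalysisConfig(
        exposure=spec(raw["exposure"]),
        outcomes=[spec(d) for d in raw["outcomes"]],
        forward_criteria=_cfg_criteria(raw.get("forward", {}),
                                       InstrumentCriteria()),
        reverse_criteria=_cfg_criteria(raw.get("reverse", {}),
                                       InstrumentCriteria(p_exposure_max=5e-6)),
        methods=tuple(raw.get("methods", DEFAULT_METHODS)),
        seed=int(raw.get("seed", 0)),
        n_boot=int(raw.get("n_boot", 1000)),
        presso_nsim=int(raw.get("presso_nsim", 1000)),
        ld=ld,
        outdir=raw.get("outdir"),
    )


def _estimate_all(hset: HarmonizedSet, methods: Sequence[str], seed: int,
                  n_boot: int) -> dict:
    out = {}
    L = len(hset)
    for m in methods:
        try:
            if m == "ivw":
                out["ivw_mre"] = ivw(hset, mode="mre")
            elif m == "ivw_fe":
                out["ivw_fe"] = ivw(hset, mode="fe")
            elif m == "egger":
                out["egger"] = mr_egger(hset)
            elif m == "wmedian":
                out["wmedian"] = weighted_median(hset, n_boot=n_boot, seed=seed)
            elif m == "cml":
                out["cml_ma"] = cml_ma(hset, seed=seed)
            elif m == "wald":
                if L == 1:
                    out["wald"] = wald_ratio(hset.pairs[0])
            else:
                raise ValueError(f"unknown method {m!r}")
        except InsufficientInstrumentsError:
            pass  # method preconditions not met at this instrument count
    return out


def run_pair(cfg: AnalysisConfig, exposure: SummaryStats, outcome: SummaryStats,
             criteria: InstrumentCriteria, direction: str) -> PairResult:
    """Run the full selection → estimation → sensitivity chain for one pair."""
    audit: list[Exclusion] = []
    n_input = len(exposure)

    # 1. exposure significance threshold
    sig = filter_by_exposure_p(exposure, criteria.p_exposure_max)
    audit.extend(Exclusion(r.snp_id, "exposure_p", "above_threshold")
                 for r in exposure if r.snp_id not in sig)

    # 2. LD clumping (requires an LD table; generated instruments are
    #    already independent, in which case the stage is a logged no-op)
    if cfg.ld is not None and len(sig):
        clumped = ld_clump(sig, cfg.ld, criteria.clump_r2_max,
                           criteria.clump_window_kb)
        audit.extend(Exclusion(r.snp_id, "clump", "ld_with_index")
                     for r in sig if r.snp_id not in clumped)
        sig = clumped

    # 3. weak-instrument filter on the exposure side
    strong_ids = []
    for r in sig:
        if r.eaf is None:
            audit.append(Exclusion(r.snp_id, "f_filter", "no_eaf"))
            continue
        if instrument_strength(r).f_stat < criteria.f_min:
            audit.append(Exclusion(r.snp_id, "f_filter", "weak_instrument"))
            continue
        strong_ids.append(r.snp_id)
    sig = sig.subset(strong_ids)

    # 4. outcome-association filter (p-values are allele-orientation
    #    invariant, so this may precede harmonization)
    keep_ids = []
    for r in sig:
        if r.snp_id in outcome and outcome[r.snp_id].pval < criteria.p_outcome_min:
            audit.append(Exclusion(r.snp_id, "outcome_p", "outcome_associated"))
        else:
            keep_ids.append(r.snp_id)
    sig = sig.subset(keep_ids)

    def _finish_not_estimable(hset_log, n_snp, surviving=()):
        return PairResult(
            exposure_label=exposure.trait_label, outcome_label=outcome.trait_label,
            direction=direction, estimates={}, sensitivity=None,
            n_snp_final=n_snp, estimable=False,
            note="fewer than 2 instruments survived selection",
            first_pass={"audit": audit + list(hset_log), "n_input": n_input,
                        "surviving_ids": list(surviving)})

    # 5. harmonization (palindrome removal, strand/swap resolution)
    try:
        hset = harmonize_set(exposure, outcome, list(sig.records))
    except EmptyInstrumentError as err:
        return _finish_not_estimable(err.exclusion_log, 0)

    # 6. Steiger directionality filter
    hset = steiger_filter(hset)
    # 7. confounder exclusion
    hset = hset.drop([s for s in hset.snp_ids if s in criteria.exclusion_list],
                     "confounder", "confounder")
    audit.extend(hset.exclusion_log)

    if len(hset) < 2:
        return _finish_not_estimable([], len(hset), surviving=hset.snp_ids)
    hset = HarmonizedSet(hset.pairs, audit)

    # estimation + sensitivity, with a single outlier-removal re-run
    estimates = _estimate_all(hset, cfg.methods, cfg.seed, cfg.n_boot)
    sens = sensitivity_report(hset, seed=cfg.seed, n_sim=cfg.presso_nsim)
    first_pass: dict = {}
    outliers: list[str] = []
    if sens.presso is not None:
        outliers.extend(sens.presso.outlier_ids)
    outliers.extend(s for s in sens.radial.outlier_ids if s not in outliers)
    if outliers:
        first_pass = {"estimates": estimates, "sensitivity": sens,
                      "outliers_removed": list(outliers)}
        reasons = {}
        if sens.presso is not None:
            reasons.update({s: "presso_outlier" for s in sens.presso.outlier_ids})
        for s in sens.radial.outlier_ids:
            reasons.setdefault(s, "radial_outlier")
        log = list(hset.exclusion_log)
        log.extend(Exclusion(s, "outlier", reasons[s]) for s in outliers)
        hset = HarmonizedSet([p for p in hset.pairs if p.snp_id not in set(outliers)],
                             log)
        if len(hset) < 2:
            return _finish_not_estimable(log[len(audit):], len(hset),
                                         surviving=hset.snp_ids)
        estimates = _estimate_all(hset, cfg.methods, cfg.seed, cfg.n_boot)
        sens = sensitivity_report(hset, seed=cfg.seed, n_sim=cfg.presso_nsim)

    res = PairResult(
        exposure_label=exposure.trait_label, outcome_label=outcome.trait_label,
        direction=direction, estimates=estimates, sensitivity=sens,
        n_snp_final=len(hset), estimable=True, first_pass=first_pass)
    # stash the audit trail for conservation checks and the audit file
    res.first_pass.setdefault("audit", list(hset.exclusion_log))
    res.first_pass["n_input"] = n_input
    res.first_pass["surviving_ids"] = hset.snp_ids
    return res


def run_bidirectional(cfg: AnalysisConfig) -> dict:
    """Run every forward and reverse pair, apply per-direction FDR, and
    (optionally) write the report tables and audit files to ``cfg.outdir``.

    Returns a dict with ``results`` (list of :class:`PairResult`) and the
    four report tables from :func:`assemble_report`.
    """
    exposure = cfg.exposure.load()
    results: list[PairResult] = []
    for spec in cfg.outcomes:
        outcome = spec.load()
        results.append(run_pair(cfg, exposure, outcome,
                                cfg.forward_criteria, "forward"))
        results.append(run_pair(cfg, outcome, exposure,
                                cfg.reverse_criteria, "reverse"))
    tables = assemble_report(results, expected_per_direction=len(cfg.outcomes))
    out = {"results": results, **tables}
    if cfg.outdir:
        _write_outputs(out, cfg.outdir)
    return out


def _write_outputs(out: dict, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("forward_forest", "reverse_forest",
                 "forward_sensitivity", "reverse_sensitivity"):
        df = out[name]
        write_table(df.to_dict(orient="records"), outdir / f"{name}.tsv")
    # machine-readable audit: one JSON line per pair
    with open(outdir / "audit.jsonl", "w") as fh:
        for r in out["results"]:
            rec = {
                "direction": r.direction,
                "exposure": r.exposure_label,
                "outcome": r.outcome_label,
                "estimable": r.estimable,
                "n_input": r.first_pass.get("n_input"),
                "n_snp_final": r.n_snp_final,
                "exclusions": [list(e) for e in r.first_pass.get("audit", [])],
            }
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
    excl_rows = []
    for r in out["results"]:
        for e in r.first_pass.get("audit", []):
            excl_rows.append({"direction": r.direction, "exposure": r.exposure_label,
                              "outcome": r.outcome_label, "snp_id": e.snp_id,
                              "stage": e.stage, "reason": e.reason})
    write_table(excl_rows, outdir / "exclusions.tsv")
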