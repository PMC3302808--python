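"""End-to-end orchestration of the population-level analysis.

Given an in-frame alignment with metadata, outgroup and region annotations,
:func:`run_population_analysis` runs, in order: haplotype collapsing, the
MaxChi recombination screen (network tests assume no recombination, so a hit
only raises a warning banner), diversity summaries and neutrality tests per
region x population with Holm-Sidak correction, statistical-parsimony
network construction and polarization, the tip/interior Fisher test (overall
and per region), the region-stratified permutation test, and the
rank-survival test.  All tables are written as TSV and JSON, with a run log
capturing seeds and versions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .netsel import (
    permutation_table_test,
    stratified_table,
    survival_mw,
    templeton_fisher,
)
from .network import build_network, classify_mutations, edge_table, parsimony_limit, polarize
from .popgen import (
    diversity_summary,
    fay_wu_H,
    fu_li_D_F,
    sidak_adjust,
    tajima_D,
)
from .recomb import maxchi, recombination_detected
from .seqdata import CodonAlignment, Region, collapse_haplotypes


@dataclass
class RunConfig:
    outdir: str | Path = "hapsel_out"
    regions: list[Region] = field(default_factory=list)
    alpha: float = 0.05
    n_perm: int = 1000
    seed: int = 0
    min_haplotypes: int = 3
    pooled: bool = True  # analyze all species together as one clade
    per_species: bool = True
    run_recombination: bool = True
    max_recomb_pairs: int | None = 200

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def _populations(aln: CodonAlignment, cfg: RunConfig) -> dict[str, CodonAlignment]:
    pops: dict[str, CodonAlignment] = {}
    if cfg.pooled:
        pops["pooled"] = aln
    if cfg.per_species:
        by_sp: dict[str, list] = {}
        for r in aln.sequences:
            if r.species:
                by_sp.setdefault(r.species, []).append(r)
        for sp, recs in by_sp.items():
            if len(recs) >= 4:
                pops[sp] = CodonAlignment(
                    recs,
                    frame_offset=aln.frame_offset,
                    outgroup=aln.outgroup,
                    regions=aln.regions,
                )
    return pops


def _region_views(aln: CodonAlignment, cfg: RunConfig) -> dict[str, CodonAlignment]:
    views = {"full": aln}
    for r in cfg.regions:
        views[r.name] = aln.subset(r)
        views[f"without_{r.name}"] = aln.complement(r)
    return views


def run_population_analysis(aln: CodonAlignment, cfg: RunConfig) -> dict:
    """Execute the full population arm and write the report bundle."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"hapsel {__version__} seed={cfg.seed} alpha={cfg.alpha}"]
    report: dict = {}

    hs = collapse_haplotypes(aln)
    log.append(f"collapsed {aln.n} sequences into {hs.h} haplotypes")

    if cfg.run_recombination:
        rec = maxchi(aln, n_perm=cfg.n_perm, seed=cfg.seed, max_pairs=cfg.max_recomb_pairs)
        hit = recombination_detected(rec, cfg.alpha)
        report["recombination"] = pd.DataFrame(
            [
                {
                    "seq_a": r.pair[0],
                    "seq_b": r.pair[1],
                    "breakpoint_site": r.best_breakpoint_site,
                    "chi2_max": r.chi2_max,
                    "p": r.p,
                    "significant": r.significant,
                }
                for r in rec
            ]
        )
        if hit:
            log.append(
                "WARNING: MaxChi detected recombination; network-based tests "
                "assume a non-recombining history"
            )
        else:
            log.append("MaxChi: no recombination detected")

    # diversity + neutrality per region x population
    div_rows, neut = [], []
    for reg_name, reg_aln in _region_views(aln, cfg).items():
        for pop_name, pop_aln in _populations(reg_aln, cfg).items():
            try:
                d = diversity_summary(pop_aln, region=reg_name, population=pop_name)
                div_rows.append(d.__dict__)
            except ValueError as e:
                log.append(f"diversity {reg_name}/{pop_name} skipped: {e}")
            for fn in (tajima_D,):
                try:
                    neut.append(fn(pop_aln, region=reg_name, population=pop_name))
                except ValueError as e:
                    log.append(f"{fn.__name__} {reg_name}/{pop_name} skipped: {e}")
            if pop_aln.outgroup is not None:
                try:
                    dD, dF = fu_li_D_F(pop_aln, region=reg_name, population=pop_name)
                    neut.extend([dD, dF])
                    neut.append(fay_wu_H(pop_aln, region=reg_name, population=pop_name))
                except ValueError as e:
                    log.append(f"polarized tests {reg_name}/{pop_name} skipped: {e}")
            else:
                log.append(
                    f"no outgroup: Fu & Li and Fay & Wu not computed for {reg_name}/{pop_name}"
                )
    defined = [r for r in neut if r.defined and r.p_raw is not None]
    adj = sidak_adjust([r.p_raw for r in defined])
    for r, a in zip(defined, adj):
        r.p_adjusted = a
    report["diversity"] = pd.DataFrame(div_rows)
    report["neutrality"] = pd.DataFrame(
        [
            {
                "statistic": r.statistic,
                "region": r.region,
                "population": r.population,
                "value": r.value,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
            }
            for r in neut
        ]
    )

    # network + selection tests
    limit = parsimony_limit(aln.length)
    log.append(f"statistical parsimony connection limit: {limit} steps")
    net = build_network(hs, limit, frame_offset=aln.frame_offset)
    if aln.outgroup is not None:
        net = polarize(net, aln.outgroup[1])
        records = classify_mutations(net, cfg.regions or None)
        report["mutations"] = edge_table(net, records)
        try:
            fisher = templeton_fisher(records)
            report["tip_interior"] = {
                "table": fisher.table.tolist(),
                "p": fisher.p,
            }
            log.append(f"tip/interior Fisher p = {fisher.p:.3g}")
        except ValueError as e:
            log.append(f"tip/interior test skipped: {e}")
        region_names = [r.name for r in cfg.regions]
        if region_names:
            if any(r.region == "" for r in records):
                region_names = region_names + [""]  # sites outside annotations
            strat = stratified_table(records, region_names)
            if (strat.sum(axis=0) > 0).all() and (strat.sum(axis=1) > 0).all():
                perm = permutation_table_test(strat, n_perm=cfg.n_perm, seed=cfg.seed)
                report["stratified_permutation"] = {
                    "table": perm.table.tolist(),
                    "chi2": perm.statistic,
                    "p": perm.p,
                }
                log.append(f"stratified permutation p = {perm.p:.3g}")
        try:
            surv = survival_mw(records, min_haplotypes=cfg.min_haplotypes)
            report["survival"] = {
                "medians": surv.medians,
                "U": surv.U,
                "Zc": surv.Zc,
                "p": surv.p,
                "method": surv.method,
            }
            log.append(
                f"survival test Zc = {surv.Zc:.3f}, p = {surv.p:.3g} ({surv.method})"
            )
        except ValueError as e:
            log.append(f"survival test not computed: {e}")
    else:
        log.append("no outgroup: network left unrooted, selection tests skipped")

    # ---- write bundle ----
    for name, obj in report.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
            obj.to_json(outdir / f"{name}.json", orient="records")
        else:
            with open(outdir / f"{name}.json", "w") as fh:
                json.dump(obj, fh, indent=1)
    (outdir / "run.log").write_text("\n".join(log) + "\n")
    report["log"] = log
    return report
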