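"""End-to-end orchestration: select -> fold -> rank -> stats -> contacts -> itc.

A :class:`PipelineConfig` holds every stage's parameters (defaults are the
documented, analysis-faithful choices), a single global seed, and the output
directory.  :func:`run_pipeline` executes the stages in order, writing one
self-describing TSV/JSON artifact per stage plus a bundle summary; a seeded
run is byte-reproducible (no timestamps in artifacts; timing goes to the log).

:func:`replicate_printed_tables` recomputes every quantity that is derivable
from the packaged printed-table fixtures alone — consensus Z_T sums, the
top-5 group summary, the folding-dG group t-test, and the thermodynamic
identity audit — and reports the deltas against the printed values.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .complex_contacts import contact_report, parse_structure
from .consensus_ranking import ZScoreRow, load_table2, rank_candidates, top_k, total_zscore, write_ranking
from .group_stats import pooled_t_test, summarize
from .hairpin_energy import delta_g_batch, load_table3
from .itc_binding import (
    ItcExperiment,
    audit_table,
    derive_thermodynamics,
    fit_one_site,
    load_table4,
    simulate_isotherm,
)
from .sequence_pool import load_table1, read_pool_tsv, select_aptamer_like, transcribe_sense
from .synthetic_data import gen_complex_pdb

log = logging.getLogger("aptascreen.pipeline")

__all__ = ["PipelineConfig", "run_pipeline", "replicate_printed_tables"]


@dataclass
class PipelineConfig:
    """Flat, human-editable configuration with one section per stage."""

    # selection
    min_arm: int = 5
    max_mismatch: int = 3
    allow_wobble: bool = False
    # z-scores
    z_sd_ddof: int = 1
    top_n: int = 5
    # contacts
    dmax_hbond: float = 3.35
    dmin_hbond: float = 2.4
    dmax_hydrophobic: float = 3.9
    keep_waters: bool = False
    planted_hbonds: int = 4
    planted_hydrophobic: int = 3
    # itc (study design: 1.4 mL cell, 1 uM protein, 10 uM titrant, 25 x 10 uL)
    itc_cell_conc: float = 1e-6
    itc_syringe_conc: float = 10e-6
    itc_n_injections: int = 25
    itc_injection_volume: float = 10e-6
    itc_cell_volume: float = 1.4e-3
    itc_temperature: float = 298.15
    itc_noise_frac: float = 0.02  # Gaussian heat noise as a fraction of |dH|
    itc_truth_row: str = "ERaptR4"
    # global
    seed: int = 0
    outdir: str = "aptascreen_out"
    pool_tsv: str | None = None  # None -> packaged printed pool
    complex_pdb: str | None = None  # None -> seeded synthetic complex

    def validate(self) -> None:
        if self.min_arm < 1:
            raise ValueError("min_arm must be >= 1")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        for name in ("dmax_hbond", "dmin_hbond", "dmax_hydrophobic"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.dmin_hbond > self.dmax_hbond:
            raise ValueError("dmin_hbond must not exceed dmax_hbond")
        if self.itc_noise_frac < 0:
            raise ValueError("itc_noise_frac must be >= 0")
        if not 1 <= self.top_n:
            raise ValueError("top_n must be >= 1")

    # -- lossless round-trip -------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_json(payload: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: PipelineConfig, strict: bool = False) -> dict:
    """Run every stage; returns the summary dict (also written to the bundle).

    ``strict`` escalates audit flags (e.g. the -RT ln Ka gap in the printed
    thermodynamic table) to hard failures.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    # stage 1: selection -----------------------------------------------------
    pool = read_pool_tsv(config.pool_tsv) if config.pool_tsv else load_table1()
    selection = select_aptamer_like(
        pool,
        min_arm=config.min_arm,
        max_mismatch=config.max_mismatch,
        allow_wobble=config.allow_wobble,
    )
    with open(outdir / "selection.tsv", "w") as fh:
        fh.write(
            f"# aptamer-likeness selection: min_arm={config.min_arm} "
            f"max_mismatch={config.max_mismatch} allow_wobble={config.allow_wobble}\n"
        )
        fh.write("id\tgene_name\tsequence\tpassed\treason\n")
        by_id = {el.id: el for el in pool}
        for rec in selection.records:
            el = by_id[rec.id]
            fh.write(f"{rec.id}\t{el.gene_name}\t{el.dna_sense}\t{rec.passed}\t{rec.reason}\n")
    log.info("selection: %d/%d retained", len(selection.selected), len(pool))

    # stage 2: folding -------------------------------------------------------
    candidates = [transcribe_sense(el) for el in selection.selected]
    folded = delta_g_batch(candidates)
    with open(outdir / "folding.tsv", "w") as fh:
        fh.write("# single-stem nearest-neighbor hairpin dG, kcal/mol (0 = open chain)\n")
        fh.write("id\tsequence\tdelta_g\n")
        for (ident, dg), cand in zip(folded, candidates):
            fh.write(f"{ident}\t{cand.rna}\t{dg:.2f}\n")

    # stage 3: consensus ranking --------------------------------------------
    table2 = load_table2()
    rows = [
        ZScoreRow(
            candidate_id=r.candidate_id,
            z_av=r.z_av,
            z_h=r.z_h,
            z_p=r.z_p,
            z_t=total_zscore(r.z_av, r.z_h, r.z_p),
            sequence=r.sequence,
        )
        for r in table2
    ]
    ranked = rank_candidates(rows)
    write_ranking(ranked, outdir / "ranking.tsv", ddof=config.z_sd_ddof)
    top = top_k(ranked, min(config.top_n, len(ranked)))
    top_ids = [rr.row.candidate_id for rr in top]
    log.info("ranking: top %d = %s", len(top_ids), ", ".join(top_ids))

    # stage 4: group statistics ----------------------------------------------
    top_summary = summarize([rr.row.z_t for rr in top], "top_candidates_zt")
    t3 = load_table3()
    apt = t3[t3.group == "aptamer"].delta_g_kcal_mol.tolist()
    rnd = t3[t3.group == "random"].delta_g_kcal_mol.tolist()
    fold_test = pooled_t_test(apt, rnd)
    stats_payload = {
        "top_candidates": {
            "ids": top_ids,
            "n": top_summary.n,
            "mean_zt": round(top_summary.mean, 4),
            "sd_zt": round(top_summary.sd, 4),
        },
        "folding_dg_t_test": {
            "t": round(fold_test.t, 4),
            "df": fold_test.df,
            "p_two_sided": round(fold_test.p_two_sided, 4),
            "direction": fold_test.direction,
        },
    }
    _write_json(stats_payload, outdir / "stats.json")

    # stage 5: contacts --------------------------------------------------------
    if config.complex_pdb:
        pdb_text = Path(config.complex_pdb).read_text()
    else:
        pdb_text = gen_complex_pdb(
            config.planted_hbonds, config.planted_hydrophobic, seed=config.seed
        )
        (outdir / "complex_synthetic.pdb").write_text(pdb_text)
    atoms = parse_structure(pdb_text, keep_waters=config.keep_waters)
    report = contact_report(
        [a for a in atoms if a.is_protein],
        [a for a in atoms if a.is_nucleic],
        dmax_hbond=config.dmax_hbond,
        dmin_hbond=config.dmin_hbond,
        dmax_hydrophobic=config.dmax_hydrophobic,
    )
    report.write_json(outdir / "contacts.json")
    report.write_tsv(outdir / "contacts.tsv")
    log.info("contacts: %d H-bonds, %d hydrophobic", report.n_hbonds, report.n_hydrophobic)

    # stage 6: itc -------------------------------------------------------------
    t4 = load_table4()
    truth_row = t4[t4.name == config.itc_truth_row]
    if truth_row.empty:
        raise ValueError(f"no thermodynamic fixture row named {config.itc_truth_row!r}")
    truth = derive_thermodynamics(
        n=float(truth_row.n.iloc[0]),
        ka=float(truth_row.ka_per_M.iloc[0]),
        dh=float(truth_row.dh_kcal_mol.iloc[0]),
        T=config.itc_temperature,
    )
    design = ItcExperiment(
        cell_conc=config.itc_cell_conc,
        syringe_conc=config.itc_syringe_conc,
        n_injections=config.itc_n_injections,
        injection_volume=config.itc_injection_volume,
        cell_volume=config.itc_cell_volume,
        temperature=config.itc_temperature,
    )
    exp = simulate_isotherm(
        truth, design, noise_sd=config.itc_noise_frac * abs(truth.dh), seed=config.seed
    )
    fit = fit_one_site(exp)
    audit = audit_table(t4)
    itc_payload = {
        "truth_row": config.itc_truth_row,
        "fit": fit.to_dict(),
        "audit": audit,
    }
    _write_json(itc_payload, outdir / "itc.json")
    if strict and (audit["n_lnka_flagged"] or audit["n_sign_anomalies"]):
        raise RuntimeError(
            f"strict mode: thermodynamic audit flagged {audit['n_lnka_flagged']} "
            f"-RT ln Ka gaps and {audit['n_sign_anomalies']} sign anomalies"
        )

    # bundle summary -----------------------------------------------------------
    summary = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "selection": {"n_input": len(pool), "n_selected": len(selection.selected)},
        "ranking_top": top_ids,
        "stats": stats_payload,
        "contacts": {"n_hbonds": report.n_hbonds, "n_hydrophobic": report.n_hydrophobic},
        "itc_fit": {
            "n": round(fit.n, 4),
            "ka_per_M": float(f"{fit.ka:.6g}"),
            "dh_kcal_mol": round(fit.dh, 3),
            "dg_kcal_mol": round(fit.dg, 3),
        },
        "audit_flags": {
            "identity": audit["n_identity_flagged"],
            "lnka": audit["n_lnka_flagged"],
            "sign": audit["n_sign_anomalies"],
        },
    }
    _write_json(summary, outdir / "summary.json")
    log.info("pipeline finished in %.2f s", time.perf_counter() - t0)
    return summary


def replicate_printed_tables() -> dict:
    """Recompute everything derivable from the packaged printed tables.

    Returns per-table deltas: consensus-sum residuals for each candidate, the
    top-5 Z_T summary, the folding-dG pooled t-test, and the thermodynamic
    identity audit.
    """
    table2 = load_table2()
    sum_deltas = {
        r.candidate_id: round(total_zscore(r.z_av, r.z_h, r.z_p) - r.z_t, 4) for r in table2
    }
    ranked = rank_candidates(list(table2))
    top5 = top_k(ranked, 5)
    top5_summary = summarize([rr.row.z_t for rr in top5], "top5_zt")

    t3 = load_table3()
    apt = t3[t3.group == "aptamer"].delta_g_kcal_mol.tolist()
    rnd = t3[t3.group == "random"].delta_g_kcal_mol.tolist()
    apt_summary = summarize(apt, "aptamer_dg")
    rnd_summary = summarize(rnd, "random_dg")
    fold_test = pooled_t_test(apt, rnd)

    audit = audit_table(load_table4())

    return {
        "zscore_table": {
            "component_sum_deltas": sum_deltas,
            "max_abs_delta": max(abs(v) for v in sum_deltas.values()),
        },
        "top5": {
            "ids": [rr.row.candidate_id for rr in top5],
            "mean_zt": round(top5_summary.mean, 4),
            "sd_zt": round(top5_summary.sd, 4),
        },
        "folding_groups": {
            "aptamer": {"n": apt_summary.n, "mean": round(apt_summary.mean, 4),
                        "sd": round(apt_summary.sd, 4)},
            "random": {"n": rnd_summary.n, "mean": round(rnd_summary.mean, 4),
                       "sd": round(rnd_summary.sd, 4)},
            "t": round(fold_test.t, 4),
            "df": fold_test.df,
            "p_two_sided": round(fold_test.p_two_sided, 4),
        },
        "thermo_audit": audit,
    }
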