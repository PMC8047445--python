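"""Orchestration of the analysis stages into reproducible runs.

Two pipelines mirror how the underlying study combines the stages:

* ``binding`` -- titration peak table -> fast-exchange selection ->
  global Kd -> expected bound fraction at the CPMG sample
  concentrations -> constrained CPMG fit (fixed pB, free dR2) ->
  kinetic rate constants;
* ``census`` -- proteome + disorder mask -> motif census -> chi-square
  enrichment statistics -> optional intersection with a binder list.

Configurations are validated up front (unknown keys rejected) and the
full configuration is echoed into the report for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

from . import binding, census as census_mod, cpmg, io as sio

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the failing stage."""


_ALLOWED_KEYS = {
    "binding": {
        "peaks", "dispersion", "residues", "temperature",
        "ligand_uM", "protein_uM", "n_boot", "seed",
    },
    "census": {"fasta", "disorder", "families", "binders", "seed"},
}


@dataclass
class RunConfig:
    pipeline: str
    params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    verbosity: int = 1

    def validate(self) -> None:
        if self.pipeline not in _ALLOWED_KEYS:
            raise ValueError(f"unknown pipeline {self.pipeline!r}")
        unknown = set(self.params) - _ALLOWED_KEYS[self.pipeline]
        if unknown:
            raise ValueError(
                f"unknown config keys for {self.pipeline!r}: {sorted(unknown)}"
            )
        required = {"binding": {"peaks"}, "census": {"fasta", "disorder"}}[
            self.pipeline
        ]
        missing = required - set(self.params)
        if missing:
            raise ValueError(f"missing config keys: {sorted(missing)}")


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Run a configured pipeline and return a structured report."""
    config.validate()
    report: dict[str, Any] = {"config": {
        "pipeline": config.pipeline, "params": dict(config.params),
        "seed": config.seed,
    }}
    if config.pipeline == "binding":
        _run_binding(config, report)
    else:
        _run_census(config, report)
    return report


def _run_binding(config: RunConfig, report: dict) -> None:
    p = config.params
    series = _stage("read_peaks")(sio.read_peak_table, p["peaks"])
    residues = p.get("residues")
    if not residues:
        residues = _stage("select_fast_exchange")(
            binding.select_fast_exchange, series
        )
    if not residues:
        raise PipelineError(
            "stage 'select_fast_exchange' failed: no fast-exchange residues"
        )
    fit = _stage("fit_global_kd")(
        binding.fit_global_kd,
        series,
        residues,
        n_boot=int(p.get("n_boot", 200)),
        boot_seed=config.seed,
    )
    report["kd_uM"] = fit.kd
    report["kd_sd_uM"] = fit.kd_sd
    report["residues_used"] = fit.residues_used
    report["ddmax_ppm"] = fit.ddmax_per_residue
    report["fit_converged"] = fit.converged

    if "dispersion" in p:
        lig = float(p.get("ligand_uM", 80.0))
        prot = float(p.get("protein_uM", 1500.0))
        pb_calc = _stage("expected_bound_fraction")(
            binding.expected_bound_fraction, fit.kd, lig, prot
        )
        report["pb_calc"] = pb_calc
        paths = p["dispersion"]
        if isinstance(paths, (str, bytes)):
            paths = [paths]
        curves = []
        for path in paths:
            ds = _stage("read_dispersion")(sio.read_dispersion_table, path)
            curves.extend(ds.curves)
        dataset = cpmg.DispersionDataset(curves)
        gfit = _stage("fit_dispersion_global")(
            cpmg.fit_dispersion_global,
            dataset,
            mode="constrained",
            fixed_p_b=pb_calc,
            seed=config.seed,
        )
        report["cpmg"] = {
            "mode": gfit.mode,
            "p_b": gfit.p_b,
            "k_ex": gfit.k_ex,
            "k_ex_sd": gfit.k_ex_sd,
            "dw_ppm": gfit.dw_ppm,
            "reduced_chi2": gfit.reduced_chi2,
        }
        rates = _stage("rates_from_exchange")(
            cpmg.rates_from_exchange,
            gfit.p_b,
            gfit.k_ex,
            lig * 1e-6,
            prot * 1e-6,
            p_b_sd=gfit.p_b_sd,
            k_ex_sd=gfit.k_ex_sd,
        )
        report["rates"] = {
            "k_on_per_M_s": rates.k_on,
            "k_off_per_s": rates.k_off,
            "k_off_sd_per_s": rates.k_off_sd,
            "kd_cpmg_uM": rates.kd * 1e6,
            "l_free_uM": rates.l_free * 1e6,
        }


def _run_census(config: RunConfig, report: dict) -> None:
    p = config.params
    proteome = _stage("read_fasta")(sio.read_fasta, p["fasta"])
    mask = _stage("read_mask")(sio.read_mask, p["disorder"], proteome)
    fam_patterns = p.get("families")
    families = None
    if fam_patterns:
        families = [
            census_mod.MotifQuery.from_pattern(f"[VI]x[VI]" if f == "auto" else f)
            for f in fam_patterns
        ]
    result = _stage("census")(census_mod.census, proteome, mask, families)
    report["total_windows"] = result.total_windows
    report["observed_totals"] = {
        db: int(result.observed_matrix(db).sum())
        for db in ("proteome", "disordered", "structured")
    }
    stats = {}
    for db in ("disordered", "structured"):
        chi2_tot, nu, pval = _stage("chi_square_total")(
            census_mod.chi_square_total,
            result.observed_matrix(db),
            result.expected_matrix(db),
        )
        stats[db] = {"chi2_tot": chi2_tot, "nu": nu, "p_value": pval}
    report["chi_square"] = stats
    report["enrichment"] = _stage("enrichment_profile")(
        census_mod.enrichment_profile, result
    )
    if p.get("binders"):
        with open(p["binders"]) as fh:
            binder_ids = [
                ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")
            ]
        counts, unknown = _stage("intersect_interactors")(
            census_mod.intersect_interactors, binder_ids, result, proteome
        )
        report["interactors_with_motif"] = counts
        report["unknown_binders"] = unknown
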