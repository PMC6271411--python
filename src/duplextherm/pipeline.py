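"""End-to-end workflow: simulate → fit → van't Hoff → salt/Δn → report.

The pipeline chains the library stages in the order a melting study runs
them: per-curve two-state fits, the Tm⁻¹ vs log₁₀(Ct/4) concentration
plot, consolidation of the two routes, salt-slope regression per duplex and
condition, counterion uptake Δn, and matched-vs-mismatched discrimination.
Outputs are a nested JSON report plus flat TSV tables; given the same seed
and inputs the JSON report is byte-identical between runs.

Two entry points:

* :func:`run_pipeline` — analyze melting-curve TSV files from a directory,
  grouped by (label, condition); curves sharing a label and condition form
  a concentration series.
* :func:`run_synthetic_study` — generate and analyze the full six-variant
  13-mer study from the embedded reported settings (1 M stabilities, salt
  slopes, representative enthalpies); this is the round-trip used for
  validation and the worked example.
"""

from __future__ import annotations

import hashlib
import json
from collections import defaultdict
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .core import ThermoParams, melting_temperature
from .fitting import (
    ConsolidatedParams,
    NoTransitionError,
    TwoStateFitResult,
    consolidate_parameters,
    fit_two_state,
    vant_hoff_from_fits,
)
from .reference import (
    DEFAULT_TRUTH_DH,
    MINUS_DG37_1M_NA,
    SALT_SLOPES,
    VARIANTS,
    variant_strands,
)
from .salt import (
    ALPHA_MG,
    ALPHA_NA,
    IonUptake,
    SaltSlope,
    discrimination,
    fit_salt_slope,
    ion_uptake_from_dg,
    minus_dg_series_from_params,
)
from .simulate import (
    MeltingCurve,
    SaltModel,
    SimulationConfig,
    config_for_salt,
    generate_ct_series,
)

__all__ = ["RunConfig", "run_pipeline", "run_synthetic_study", "write_report"]

UNITS_NOTE = (
    "temperatures degC at I/O (K internally); dH kcal/mol; dS cal/mol/K; "
    "dG37 kcal/mol at 310.15 K; Ct is TOTAL strand concentration (M); "
    "salt slopes kcal/mol per log10[M] decade"
)

#: Discrimination pairs reported by default: (matched, mismatched).
DEFAULT_DISCRIMINATION_PAIRS = (
    ("G·C", "G·T"),
    ("A·T", "G·T"),
    ("D·T", "G·T"),
    ("I·C", "I·T"),
)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    input_dir: str | None = None
    output_dir: str = "duplextherm_out"
    seed: int = 0
    noise_sd: float = 0.002
    alpha_na: float = ALPHA_NA
    alpha_mg: float = ALPHA_MG
    two_state_threshold: float = 0.15
    salt_concentrations: tuple[float, ...] = (0.03, 0.1, 0.3, 1.0)
    ct_list: tuple[float, ...] = (2e-6, 1e-5, 5e-5, 2e-4)
    report_ct: float = 1e-5  # Ct at which report Tm values are quoted
    species: str = "Na+"

    def __post_init__(self) -> None:
        if self.two_state_threshold <= 0 or self.noise_sd < 0:
            raise ValueError("thresholds must be positive and noise_sd non-negative")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _params_dict(p: ThermoParams) -> dict:
    return {"dH": p.dH, "dS": p.dS, "dG37": p.dG37}


def _fit_dict(f: TwoStateFitResult) -> dict:
    return {
        "params": _params_dict(f.params),
        "baselines": {"b_ds": f.b_ds, "m_ds": f.m_ds, "b_ss": f.b_ss, "m_ss": f.m_ss},
        "Tm_K": f.Tm,
        "Ct_M": f.Ct,
        "sse": f.sse,
        "converged": f.converged,
        "n_iter": f.n_iter,
    }


def _consolidated_dict(c: ConsolidatedParams) -> dict:
    return {
        "params": _params_dict(c.params),
        "curve_fit": _params_dict(c.curve_fit_params),
        "vant_hoff": _params_dict(c.vant_hoff_params),
        "two_state_flag": c.two_state_flag,
        "dh_discrepancy": c.dh_discrepancy,
    }


def _slope_dict(s: SaltSlope, uptake: IonUptake) -> dict:
    return {
        "slope": s.slope,
        "stderr": s.stderr,
        "intercept_1M": s.intercept,
        "r_squared": s.r_squared,
        "delta_n": uptake.delta_n,
        "delta_n_reported": uptake.delta_n_reported,
        "alpha": uptake.alpha,
    }


def analyze_ct_series(
    curves: list[MeltingCurve], two_state_threshold: float = 0.15
) -> tuple[list[TwoStateFitResult], ConsolidatedParams]:
    """Fit every curve of one concentration series and consolidate."""
    fits = []
    for curve in curves:
        try:
            fits.append(fit_two_state(curve))
        except NoTransitionError:
            continue
    if not fits:
        raise NoTransitionError("no curve in the series shows a transition")
    vh = vant_hoff_from_fits(fits)
    consolidated = consolidate_parameters(fits, vh, dh_tolerance=two_state_threshold)
    return fits, consolidated


def run_synthetic_study(config: RunConfig) -> dict:
    """Generate and analyze the full six-variant synthetic 13-mer study.

    For each X·Y variant, curves are generated at every salt concentration
    and strand concentration from the embedded reported settings, fitted and
    consolidated; per-variant salt slopes, Δn and discrimination follow.
    """
    alpha = config.alpha_mg if config.species == "Mg2+" else config.alpha_na
    slope_key = config.species if config.species in SALT_SLOPES else "Na+"
    streams = np.random.SeedSequence(config.seed).spawn(len(VARIANTS))
    duplexes: dict[str, dict] = {}
    per_variant_params: dict[str, dict[float, ConsolidatedParams]] = {}
    for variant, stream in zip(VARIANTS, streams):
        top, bottom = variant_strands(variant)
        model = SaltModel(
            minus_dg37_1M=MINUS_DG37_1M_NA[variant],
            slope=SALT_SLOPES[slope_key][variant][0],
            alpha=alpha,
            species=config.species,
        )
        base = SimulationConfig(
            truth=ThermoParams.from_dh_dg37(
                DEFAULT_TRUTH_DH[variant], -MINUS_DG37_1M_NA[variant]
            ),
            noise_sd=config.noise_sd,
            Ct_list=config.ct_list,
            salt_model=model,
            label=variant,
            seed=int(stream.generate_state(1)[0] % (2**31)),
        )
        variant_report: dict = {"top": top, "bottom": bottom, "conditions": {}}
        per_variant_params[variant] = {}
        for conc in config.salt_concentrations:
            sub = config_for_salt(base, conc)
            curves = generate_ct_series(sub)
            fits, consolidated = analyze_ct_series(curves, config.two_state_threshold)
            per_variant_params[variant][conc] = consolidated
            variant_report["conditions"][f"{conc:g}"] = {
                "truth": _params_dict(sub.truth),
                "fits": [_fit_dict(f) for f in fits],
                "consolidated": _consolidated_dict(consolidated),
            }
        series = minus_dg_series_from_params(
            config.species,
            [
                (conc, per_variant_params[variant][conc].params)
                for conc in config.salt_concentrations
            ],
            label=variant,
        )
        slope = fit_salt_slope(series)
        uptake = ion_uptake_from_dg(slope.slope, alpha=alpha)
        variant_report["salt"] = _slope_dict(slope, uptake)
        duplexes[variant] = variant_report

    disc: list[dict] = []
    for match, mismatch in DEFAULT_DISCRIMINATION_PAIRS:
        for conc in config.salt_concentrations:
            pm = per_variant_params[match][conc].params
            pmm = per_variant_params[mismatch][conc].params
            tm_m = melting_temperature(pm.dH, pm.dS, config.report_ct)
            tm_mm = melting_temperature(pmm.dH, pmm.dS, config.report_ct)
            ddg, dtm = discrimination(pm, tm_m, pmm, tm_mm)
            disc.append(
                {
                    "match": match,
                    "mismatch": mismatch,
                    "concentration_M": conc,
                    "ddG37": ddg,
                    "dTm_K": dtm,
                }
            )

    return {
        "schema_version": 1,
        "units": UNITS_NOTE,
        "provenance": {
            "package_version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "mode": "synthetic_study",
        },
        "duplexes": duplexes,
        "discrimination": disc,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run the analysis on melting-curve TSV files, or the synthetic study.

    With ``config.input_dir`` set, every ``*.tsv`` file in it is read as a
    melting curve; curves sharing (label, condition) form one concentration
    series. Without an input directory the built-in synthetic study runs.
    """
    if config.input_dir is None:
        return run_synthetic_study(config)
    from .io import read_melting_curve

    paths = sorted(Path(config.input_dir).glob("*.tsv"))
    if not paths:
        raise FileNotFoundError(
            f"no melting-curve TSV files found in {config.input_dir!r}"
        )
    groups: dict[tuple[str, str], list[MeltingCurve]] = defaultdict(list)
    for path in paths:
        curve = read_melting_curve(path)
        groups[(curve.label, curve.condition.tag)].append(curve)

    duplexes: dict[str, dict] = defaultdict(lambda: {"conditions": {}})
    by_label_species: dict[tuple[str, str, float], ConsolidatedParams] = {}
    for (label, tag), curves in sorted(groups.items()):
        fits, consolidated = analyze_ct_series(curves, config.two_state_threshold)
        cond = curves[0].condition
        duplexes[label]["conditions"][tag] = {
            "fits": [_fit_dict(f) for f in fits],
            "consolidated": _consolidated_dict(consolidated),
        }
        key = (label, f"{cond.salt_species}|EtOH{cond.ethanol_M:g}")
        by_label_species[(*key, cond.salt_conc_M)] = consolidated

    # salt regression per duplex per (species, solvent) with >= 3 concentrations
    salt_groups: dict[tuple[str, str], list[tuple[float, ConsolidatedParams]]] = defaultdict(list)
    for (label, species_tag, conc), consolidated in by_label_species.items():
        salt_groups[(label, species_tag)].append((conc, consolidated))
    for (label, species_tag), entries in sorted(salt_groups.items()):
        if len(entries) < 3:
            continue
        species = species_tag.split("|")[0]
        alpha = config.alpha_mg if species == "Mg2+" else config.alpha_na
        series = minus_dg_series_from_params(
            species, [(c, p.params) for c, p in sorted(entries)], label=label
        )
        slope = fit_salt_slope(series)
        uptake = ion_uptake_from_dg(slope.slope, alpha=alpha)
        duplexes[label].setdefault("salt", {})[species_tag] = _slope_dict(slope, uptake)

    return {
        "schema_version": 1,
        "units": UNITS_NOTE,
        "provenance": {
            "package_version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "mode": "input_dir",
            "n_curves": len(paths),
        },
        "duplexes": dict(duplexes),
    }


def write_report(report: dict, output_dir: str | Path) -> Path:
    """Write the JSON report and flat TSV summaries; returns the JSON path.

    JSON is written with sorted keys and no timestamps, so identical runs
    produce byte-identical files.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    json_path = out / "report.json"
    json_path.write_text(
        json.dumps(report, sort_keys=True, indent=1) + "\n", encoding="utf-8"
    )
    rows = [
        "# " + report["units"],
        "duplex\tcondition\tslope\tstderr\tintercept_1M\tr_squared\tdelta_n\tdelta_n_reported",
    ]
    for label, entry in sorted(report.get("duplexes", {}).items()):
        salt = entry.get("salt")
        if not salt:
            continue
        salt_items = salt.items() if "slope" not in salt else [("default", salt)]
        for tag, s in salt_items:
            rows.append(
                f"{label}\t{tag}\t{s['slope']:.6g}\t{s['stderr']:.6g}\t"
                f"{s['intercept_1M']:.6g}\t{s['r_squared']:.6g}\t"
                f"{s['delta_n']:.6g}\t{s['delta_n_reported']:g}"
            )
    (out / "salt_slopes.tsv").write_text("\n".join(rows) + "\n", encoding="utf-8")
    return json_path
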