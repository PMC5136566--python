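"""End-to-end analysis pipeline: design check, fit, comparison, profiles.

Orchestrates the full analysis of one (or two combinable) detection
sessions: a-priori design screen, multi-start maximum-likelihood fit of
the hazard model, logistic-baseline comparison with BIC, likelihood-ratio
goodness of fit, and per-parameter profile-likelihood curves with
confidence intervals and identifiability labels.  Results are collected
in a hierarchical bundle (JSON-serialisable) plus a human-readable
report.
"""

from __future__ import annotations

import importlib.metadata
from pathlib import Path

import numpy as np

from . import baseline, identifiability, inference, io
from .data import Dataset
from .model import HazardParams, ModelConstants, ParameterSpace, default_parameter_space

__all__ = ["DEFAULT_CONFIG", "run_pipeline", "write_report", "plot_profiles"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "n_starts": 100,
    "n_grid": 41,
    "T": 1000.0,
    "tau_s": 1.5,
    "level": 0.95,
    "flat_tol": 0.01,
    "amp_round": 0.01,
    "amp_overlap_min": 0.5,
    "bounds_lower": None,  # 6-vector override of the feasible space
    "bounds_upper": None,
}


def _space_from_config(config: dict) -> ParameterSpace:
    default = default_parameter_space()
    lower = config.get("bounds_lower") or default.lower
    upper = config.get("bounds_upper") or default.upper
    return ParameterSpace(np.asarray(lower, float), np.asarray(upper, float))


def run_pipeline(
    datasets: list[Dataset],
    output_dir=None,
    config: dict | None = None,
) -> dict:
    """Run the full analysis and return the result bundle.

    ``datasets`` is one elementary dataset, or two same-design sessions
    to be screened and merged first; a failed merge returns a bundle with
    only the rejection report.  When ``output_dir`` is given, the bundle
    (JSON), the report (text) and the profile plot (PDF) are written
    there.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    space = _space_from_config(cfg)
    constants = ModelConstants(tau_s=cfg["tau_s"], T=cfg["T"])

    bundle: dict = {"provenance": _provenance(cfg)}

    if len(datasets) == 1:
        dataset = datasets[0]
    elif len(datasets) == 2:
        report = inference.combine_datasets(
            datasets[0],
            datasets[1],
            amp_overlap_min=cfg["amp_overlap_min"],
            amp_round=cfg["amp_round"],
        )
        bundle["combine"] = {
            "accepted": report.accepted,
            "failures": [list(f) for f in report.failures],
        }
        if not report.accepted:
            _write_outputs(bundle, None, output_dir)
            return bundle
        dataset = report.dataset
    else:
        raise ValueError("run_pipeline accepts one or two datasets")

    # a-priori design screen
    design_report = identifiability.check_design_pw_variation(dataset, space=space)
    bundle["design_check"] = {
        "structural_warning": design_report.structural_warning,
        "pulse_widths": list(design_report.pulse_widths),
        "affected": list(design_report.affected),
        "set_ratio": design_report.set_ratio,
        "messages": list(design_report.messages),
    }

    # hazard-model fit
    fit = inference.fit_hazard_model(
        dataset, space=space, constants=constants,
        n_starts=cfg["n_starts"], seed=cfg["seed"],
    )
    bundle["fit"] = {
        "theta_hat": dict(zip(inference.PARAM_NAMES, fit.theta_hat.to_array())),
        "nll_hat": fit.nll_hat,
        "n_starts": fit.start_count,
        "boundary_flags": dict(zip(inference.PARAM_NAMES, fit.boundary)),
        "any_boundary": fit.any_boundary,
        "converged": fit.converged,
        "sorted_nlls": fit.sorted_nlls,
    }

    # baseline comparison and goodness of fit
    comparison = baseline.compare_models(dataset, fit.theta_hat, constants)
    bundle["comparison"] = {
        "nll_hm": comparison.nll_hm,
        "nll_logistic": comparison.nll_logistic,
        "bic_hm": comparison.bic_hm,
        "bic_logistic": comparison.bic_logistic,
        "delta_bic": comparison.delta,
        "n_obs": comparison.n_obs,
        "n_params_hm": comparison.n_params_hm,
        "n_params_logistic": comparison.n_params_logistic,
    }
    try:
        g2, df, p = baseline.goodness_of_fit(
            dataset, fit.theta_hat, constants, amp_round=cfg["amp_round"]
        )
        bundle["gof"] = {"g2": g2, "df": df, "p": p}
    except ValueError as exc:
        bundle["gof"] = {"error": str(exc)}

    # profile likelihoods
    profiler = identifiability.Profiler(dataset, fit, space=space, constants=constants)
    curves = []
    profiles: dict = {}
    for i, name in enumerate(inference.PARAM_NAMES):
        curve = profiler.curve(i, n_grid=cfg["n_grid"])
        curve.ci = identifiability.profile_confidence_interval(curve, cfg["level"])
        cls = identifiability.classify_identifiability(
            curve, flat_tol=cfg["flat_tol"], level=cfg["level"]
        )
        curve.label = cls.label
        curve.flat_ratio = cls.flat_ratio
        curves.append(curve)
        profiles[name] = {
            "grid": curve.grid,
            "lpl": curve.lpl,
            "nll_hat": curve.nll_hat,
            "theta_hat_value": curve.theta_hat_value,
            "improved": curve.improved,
            "ci": {
                "lower": curve.ci.lower,
                "upper": curve.ci.upper,
                "open_low": curve.ci.open_low,
                "open_high": curve.ci.open_high,
                "level": curve.ci.level,
                "multimodal": curve.ci.multimodal,
            },
            "label": curve.label,
            "flat_ratio": curve.flat_ratio,
        }
    bundle["profiles"] = profiles

    _write_outputs(bundle, curves, output_dir)
    return bundle


def _provenance(cfg: dict) -> dict:
    try:
        version = importlib.metadata.version("nocifit")
    except importlib.metadata.PackageNotFoundError:
        version = "unknown"
    return {
        "config": {k: (list(v) if isinstance(v, (tuple, np.ndarray)) else v)
                   for k, v in cfg.items()},
        "seed": cfg.get("seed"),
        "versions": {"nocifit": version, "numpy": np.__version__},
    }


def _write_outputs(bundle: dict, curves, output_dir) -> None:
    if output_dir is None:
        return
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.save_bundle(bundle, out / "results.json")
    (out / "report.txt").write_text(write_report(bundle))
    if curves:
        try:
            plot_profiles(curves, out / "profiles.pdf")
        except Exception:  # plotting is best-effort
            pass


def write_report(bundle: dict, path=None) -> str:
    """Render a result bundle as a human-readable text report."""
    lines = ["nocifit analysis report", "=" * 60]

    combine = bundle.get("combine")
    if combine is not None:
        if combine["accepted"]:
            lines.append("Dataset combination: ACCEPTED")
        else:
            lines.append("Dataset combination: REJECTED")
            for combo, criterion, detail in combine["failures"]:
                lines.append(f"  [{combo}] {criterion}: {detail}")
            text = "\n".join(lines) + "\n"
            if path is not None:
                Path(path).write_text(text)
            return text

    check = bundle.get("design_check", {})
    for msg in check.get("messages", []):
        lines.append(f"DESIGN WARNING: {msg}")

    fit = bundle.get("fit")
    if fit:
        lines.append("")
        lines.append("Hazard-model fit")
        lines.append(f"  -log L_hat = {fit['nll_hat']:.6f}  "
                     f"({fit['n_starts']} starts, converged={fit['converged']})")
        if fit.get("any_boundary"):
            flagged = [k for k, v in fit["boundary_flags"].items() if v]
            lines.append(f"  BOUNDARY ESTIMATE for: {', '.join(flagged)} "
                         "-- interpret profiles with caution")
        profiles = bundle.get("profiles", {})
        lines.append(f"  {'parameter':<10}{'estimate':>14}{'CI low':>14}"
                     f"{'CI high':>14}  label")
        for name, value in fit["theta_hat"].items():
            prof = profiles.get(name)
            if prof:
                ci = prof["ci"]
                lo = f"{ci['lower']:.5g}" + ("(open)" if ci["open_low"] else "")
                hi = f"{ci['upper']:.5g}" + ("(open)" if ci["open_high"] else "")
                label = prof["label"]
                if prof.get("flat_ratio"):
                    label += f" (flat-interval ratio {prof['flat_ratio']:.3f})"
            else:
                lo = hi = "-"
                label = "-"
            lines.append(f"  {name:<10}{value:>14.6g}{lo:>14}{hi:>14}  {label}")

    comp = bundle.get("comparison")
    if comp:
        lines.append("")
        lines.append("Model comparison (BIC; smaller is better)")
        lines.append(f"  hazard model : BIC = {comp['bic_hm']:.3f} "
                     f"(nP = {comp['n_params_hm']}, -log L = {comp['nll_hm']:.3f})")
        lines.append(f"  logistic     : BIC = {comp['bic_logistic']:.3f} "
                     f"(nP = {comp['n_params_logistic']}, "
                     f"-log L = {comp['nll_logistic']:.3f})")
        winner = "hazard model" if comp["delta_bic"] < 0 else "logistic"
        lines.append(f"  delta BIC = {comp['delta_bic']:.3f} -> favours {winner}")

    gof = bundle.get("gof")
    if gof and "g2" in gof:
        lines.append("")
        lines.append(f"Goodness of fit vs saturated model: "
                     f"G2 = {gof['g2']:.3f}, df = {gof['df']}, p = {gof['p']:.4f}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def plot_profiles(curves, path) -> None:
    """Plot LPL vs parameter (log axis) with threshold line and estimate."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy import stats as sps

    fig, axes = plt.subplots(2, 3, figsize=(12, 7))
    for curve, ax in zip(curves, axes.ravel()):
        ax.plot(curve.grid, curve.lpl, "k.-", lw=1, ms=3)
        level = curve.ci.level if curve.ci is not None else 0.95
        threshold = 2 * curve.nll_hat + sps.chi2.ppf(level, 1)
        ax.axhline(threshold, ls="--", color="0.4")
        ax.plot(
            [curve.theta_hat_value], [2 * curve.nll_hat], "rx", ms=8, mew=2
        )
        ax.set_xscale("log")
        ax.set_xlabel(curve.param_name)
        ax.set_ylabel("-2 log PL")
        if curve.label:
            ax.set_title(curve.label.replace("_", " "), fontsize=9)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
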