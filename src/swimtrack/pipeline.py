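"""End-to-end orchestration: simulate -> filter -> regularize -> correct ->
metrics -> circular tests -> persistence model.

Every stage logs rows in/out into a run manifest, and a single seed in
the configuration drives all stochastic behaviour (simulation and
permutation tests), so that two runs with the same configuration
produce byte-identical product tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import circular, currents, gamm, metrics, ssm, synthetic, trackio


@dataclass
class RunConfig:
    """Defaults follow the study constants: 10 km island buffer, 24-h
    regularization step, 1 km sargassum radius."""

    scenario: str = "jan"
    n_turtles: int = 30
    seed: int = 0
    duration_days: float = 15.0
    buffer_radius_km: float = 10.0
    declination_deg: float = 0.0
    sargassum_radius_km: float = 1.0
    watson_permutations: int = 9999
    gamm_k: int = 25
    gamm_candidates: tuple = gamm.CANDIDATE_ORDER
    arma_max_order: int = 4

    def content_hash(self):
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True,
                                         default=str).encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage, message):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def simulate(config: RunConfig, outdir) -> dict:
    """Generate a cohort and write fixes, field(s), truth and covariates.

    scenario "both" writes a January-like and a July-like cohort into a
    single data set (one field file per period); the per-period seeds
    are derived from the single run seed.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if config.n_turtles < 1:
        raise StageError("simulate", "n_turtles must be >= 1")
    if config.scenario == "both":
        n_jul = max(1, config.n_turtles // 3)
        parts = [("jan", config.n_turtles - n_jul, config.seed),
                 ("jul", n_jul, config.seed + 10007)]
    else:
        parts = [(config.scenario, config.n_turtles, config.seed)]
    fixes, truth, daily, covs = [], [], [], []
    n_fixes = 0
    for scen, n, seed in parts:
        cohort = synthetic.make_cohort(scen, n, seed=seed,
                                       duration_days=config.duration_days)
        suffix = f"_{scen}" if config.scenario == "both" else ""
        trackio.write_field(cohort["field"].dataset, out / f"field{suffix}.nc")
        fixes.append(cohort["fixes"])
        truth.append(cohort["truth"])
        daily.append(cohort["daily_truth"])
        covs.append(cohort["covariates"])
        n_fixes += len(cohort["fixes"])
    trackio.write_fixes(pd.concat(fixes, ignore_index=True), out / "fixes.csv")
    tf = pd.concat(truth, ignore_index=True)
    tf["time"] = pd.to_datetime(tf["time"]).dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
    tf.to_csv(out / "truth_fine.csv", index=False, float_format="%.10g")
    dt = pd.concat(daily, ignore_index=True)
    dt["time"] = pd.to_datetime(dt["time"]).dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
    dt.to_csv(out / "truth_daily.csv", index=False, float_format="%.10g")
    pd.concat(covs, ignore_index=True).to_csv(out / "covariates.csv", index=False,
                                              float_format="%.10g")
    manifest = {
        "stage": "simulate",
        "config": asdict(config),
        "config_hash": config.content_hash(),
        "n_animals": int(config.n_turtles),
        "n_fixes": int(n_fixes),
    }
    (out / "manifest_simulate.json").write_text(json.dumps(manifest, indent=1,
                                                           default=str))
    return manifest


def analyze(config: RunConfig, datadir, outdir=None) -> dict:
    """Run the full analysis chain on a simulated (or conforming) data set."""
    data = Path(datadir)
    out = Path(outdir) if outdir else data
    out.mkdir(parents=True, exist_ok=True)
    counts = {}
    warnings = []

    fixes = trackio.read_fixes(data / "fixes.csv")
    if fixes.empty:
        raise StageError("ingest", "no fixes found")
    fields = [trackio.read_field(p) for p in sorted(data.glob("field*.nc"))]
    if not fields:
        raise StageError("ingest", "no field file found")

    def field_for(date):
        """The field whose time axis covers (or is nearest to) a date."""
        best, bestd = fields[0], np.inf
        for f in fields:
            t = pd.to_datetime(f["time"].values)
            if t[0] <= date <= t[-1]:
                return f
            d = min(abs((t[0] - date).days), abs((t[-1] - date).days))
            if d < bestd:
                best, bestd = f, d
        return best
    covariates = (pd.read_csv(data / "covariates.csv", dtype={"animal_id": str})
                  if (data / "covariates.csv").exists() else None)
    island = synthetic.island_polygon()
    counts["fixes_in"] = len(fixes)

    # dispersal labels from raw fixes
    labels = metrics.classify_dispersal(fixes, island, config.buffer_radius_km)
    labels.to_csv(out / "dispersal_labels.csv", index=False)
    dispersive_ids = set(labels.loc[labels["label"] == "dispersive", "animal_id"])

    # initial headings (all animals with >= 2 fixes)
    head_rows = []
    for aid, sub in fixes.groupby("animal_id", sort=True):
        if len(sub) >= 2:
            try:
                h = metrics.initial_heading(sub, config.declination_deg)
                head_rows.append({"animal_id": aid, "initial_heading_deg": h})
            except ValueError:
                warnings.append(f"{aid}: initial heading undefined")
    pd.DataFrame(head_rows).to_csv(out / "initial_headings.csv", index=False,
                                   float_format="%.10g")

    # buffer filter + regularization of dispersive animals
    disp_fixes = fixes[fixes["animal_id"].isin(dispersive_ids)].reset_index(drop=True)
    retained, filter_report = ssm.buffer_filter(disp_fixes, island,
                                                config.buffer_radius_km)
    filter_report.to_csv(out / "buffer_filter_report.csv", index=False)
    counts["fixes_dispersive"] = len(disp_fixes)
    counts["fixes_retained"] = len(retained)
    tracks, fits = ssm.regularize(retained)
    counts["daily_positions"] = len(tracks)
    if tracks.empty:
        warnings.append("no dispersive animals usable; current correction, "
                        "circular tests and persistence model skipped")
        _write_manifest(out, config, counts, warnings)
        return {"counts": counts, "warnings": warnings, "skipped": True}

    # decomposition + annotation + persistence
    decomps, annots, series_parts = {}, {}, []
    for aid, track in tracks.groupby("animal_id", sort=True):
        track = track.reset_index(drop=True)
        if len(track) < 2:
            warnings.append(f"{aid}: single daily position, skipped")
            continue
        fld = field_for(pd.Timestamp(track["date"].iloc[0]))
        dec = currents.decompose(track, fld)
        ann = currents.annotate(track, fld, config.sargassum_radius_km)
        decomps[aid] = dec
        annots[aid] = ann
        if len(dec) >= 3:
            ps = metrics.persistence_series(dec)
            ps = ps.merge(ann, on=["animal_id", "date"], how="left")
            ps["cur_speed"] = dec.set_index("date").loc[ps["date"], "cur_speed"].to_numpy()
            series_parts.append(ps)

    daily_all = pd.concat([d for d in decomps.values()], ignore_index=True)
    trackio.write_daily_products(daily_all.rename(columns={"date": "date"}),
                                 out / "daily_products.csv",
                                 out / "trajectories.geojson")
    counts["decomposition_rows"] = int(sum(len(d) for d in decomps.values()))

    # Table-1-style summary
    summary = metrics.cohort_summary(tracks, decomps, annots, covariates)
    trackio.write_summary_tsv(summary, out / "track_summary.tsv")

    # circular statistics battery
    groups = {}
    if covariates is not None and "period" in covariates.columns:
        period_of = dict(zip(covariates["animal_id"].astype(str), covariates["period"]))
    else:
        period_of = {aid: "all" for aid in decomps}
    for aid, dec in decomps.items():
        per = period_of.get(str(aid), "all")
        g = groups.setdefault(per, {"headings": [], "currents": []})
        ok = np.isfinite(dec["ground_east"])
        g["headings"].extend(
            np.degrees(np.arctan2(dec.loc[ok, "ground_east"], dec.loc[ok, "ground_north"])) % 360)
        okc = np.isfinite(dec["cur_east"])
        g["currents"].extend(
            np.degrees(np.arctan2(dec.loc[okc, "cur_east"], dec.loc[okc, "cur_north"])) % 360)
    test_rows = circular.heading_current_contrast(
        groups, permutations=config.watson_permutations, seed=config.seed + 1)
    for per, g in sorted(groups.items()):
        m, sd, rbar = circular.circ_mean_sd(g["headings"])
        mc, sdc, _ = circular.circ_mean_sd(g["currents"])
        test_rows.append({"contrast": f"descriptive ({per})",
                          "heading_mean": m, "heading_sd": sd,
                          "current_mean": mc, "current_sd": sdc})
    pd.DataFrame(test_rows).to_csv(out / "circular_tests.csv", index=False,
                                   float_format="%.10g")

    # persistence model
    gamm_report = {}
    if series_parts:
        series = pd.concat(series_parts, ignore_index=True)
        if covariates is not None:
            series = series.merge(
                covariates[["animal_id", "period", "weight_kg"]],
                on="animal_id", how="left")
        series.to_csv(out / "persistence_series.csv", index=False,
                      float_format="%.10g")
        counts["persistence_rows"] = len(series)
        candidates = [c for c in config.gamm_candidates if c in series.columns
                      and series[c].notna().mean() >= 0.6]
        dropped_cands = [c for c in config.gamm_candidates if c not in candidates]
        if dropped_cands:
            warnings.append(f"candidates absent from data: {dropped_cands}")
        base = gamm.GammSpec(fixed_effects=tuple(candidates), k=config.gamm_k,
                             arma=(0, 0), method="ML")
        first = gamm.fit(series, base)
        resids = [first.residuals[np.concatenate(p)] for _, p in first.design.runs]
        (pq, arma_table) = gamm.select_arma(resids, config.arma_max_order)
        arma_table.to_csv(out / "arma_selection.csv", index=False,
                          float_format="%.10g")
        final_spec = gamm.GammSpec(fixed_effects=tuple(candidates), k=config.gamm_k,
                                   arma=pq, method="ML")
        final, trace = gamm.backward_eliminate(series, final_spec)
        trace.to_csv(out / "elimination_trace.tsv", sep="\t", index=False,
                     float_format="%.10g")
        final.summary_table().to_csv(out / "gamm_coefficients.tsv", sep="\t",
                                     index=False, float_format="%.10g")
        grid = gamm.prediction_grid(final)
        grid.to_csv(out / "prediction_grid.csv", index=False, float_format="%.6g")
        gamm_report = {"arma": list(pq), "aic": final.aic,
                       "retained": [c for c in final.spec.fixed_effects]}
    else:
        warnings.append("no persistence series long enough; model skipped")

    _write_manifest(out, config, counts, warnings, extra={"gamm": gamm_report})
    return {"counts": counts, "warnings": warnings, "gamm": gamm_report,
            "skipped": False}


def _write_manifest(out, config, counts, warnings, extra=None):
    manifest = {"stage": "analyze", "config": asdict(config),
                "config_hash": config.content_hash(), "counts": counts,
                "warnings": warnings}
    if extra:
        manifest.update(extra)
    (Path(out) / "manifest_analyze.json").write_text(
        json.dumps(manifest, indent=1, default=str))


def report(outdir) -> str:
    """Human-readable markdown summary of a completed run."""
    out = Path(outdir)
    lines = ["# swimtrack run report", ""]
    missing = 0

    def section(title):
        lines.append(f"## {title}")

    section("Cohort")
    f = out / "dispersal_labels.csv"
    if f.exists():
        lab = pd.read_csv(f)
        vc = lab["label"].value_counts()
        for k, v in vc.items():
            lines.append(f"- {k}: {v}")
    else:
        lines.append("- unavailable")
        missing += 1
    lines.append("")

    section("Circular statistics")
    f = out / "circular_tests.csv"
    if f.exists():
        ct = pd.read_csv(f)
        for _, r in ct.iterrows():
            if isinstance(r.get("u2"), float) and np.isfinite(r.get("u2", np.nan)):
                lines.append(f"- {r['contrast']}: U2={r['u2']:.3f}, p={r['p']:.4g} "
                             f"(n={int(r['n'])}, m={int(r['m'])})")
            elif "heading_mean" in ct.columns and np.isfinite(r.get("heading_mean", np.nan)):
                lines.append(f"- {r['contrast']}: headings {r['heading_mean']:.0f} deg "
                             f"(+-{r['heading_sd']:.0f} SD), currents "
                             f"{r['current_mean']:.0f} deg (+-{r['current_sd']:.0f} SD)")
    else:
        lines.append("- unavailable")
        missing += 1
    lines.append("")

    section("Persistence model")
    f = out / "gamm_coefficients.tsv"
    if f.exists():
        co = pd.read_csv(f, sep="\t")
        for _, r in co.iterrows():
            if np.isfinite(r.get("estimate", np.nan)):
                lines.append(f"- {r['term']}: {r['estimate']:.3g} "
                             f"(SE {r['se']:.3g}, p={r['p']:.3g})")
            else:
                lines.append(f"- {r['term']}: EDF={r.get('edf', float('nan')):.2f}, "
                             f"p={r['p']:.3g}")
        tr = out / "elimination_trace.tsv"
        if tr.exists():
            t = pd.read_csv(tr, sep="\t")
            lines.append(f"- elimination steps: {len(t) - 1}; final AIC "
                         f"{t['aic'].iloc[-1]:.2f}")
    else:
        lines.append("- unavailable")
        missing += 1
    lines.append("")
    text = "\n".join(lines)
    return text if missing < 3 else text + "\n(all sections unavailable)\n"
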