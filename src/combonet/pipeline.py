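"""Top-level pipeline: reconstruct -> (nulls) -> viability -> dose -> optimize -> power."""

from __future__ import annotations

import json
import math
from pathlib import Path

from . import io
from .cnr import final_model
from .combos import CellLineModel, OptimizerConfig, power_analysis, rank_all_triples, select_controls
from .dose import dose_params_dict, fit_dose_params
from .nulls import empirical_pvalue, null_ensemble
from .synthetic import generate_ground_truth, make_study_design, simulate_dataset
from .viability import fit_viability_model


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the full pipeline from a configuration dictionary.

    Synthetic mode (``config["synthetic"]`` present) generates its own data;
    otherwise response/viability tables are read from the configured paths.
    Every artifact is written under ``outdir``; a manifest records seeds and
    input hashes.  Missing viability data stops the pipeline cleanly after
    reconstruction.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest: dict = {"seed": seed, "stages": [], "inputs": {}}
    artifacts: dict = {}

    def _stage(name):
        manifest["stages"].append(name)

    try:
        if "synthetic" in config:
            syn = config["synthetic"] or {}
            design = make_study_design(
                combo_count=int(syn.get("combos", 17)), seed=seed
            )
            truth = generate_ground_truth(
                design,
                n_edges=int(syn.get("edges", 16)),
                n_diffs=int(syn.get("diffs", 13)),
                seed=seed,
            )
            responses, viability = simulate_dataset(
                truth,
                design,
                noise_sd=float(syn.get("noise", 0.1)),
                viability_noise_sd=float(syn.get("viability_noise", 0.05)),
                replicates=int(syn.get("replicates", 3)),
                seed=seed,
            )
            io.save_design(design, outdir / "design.json")
            io.save_ground_truth(truth, outdir / "truth.json")
            for ln, R in responses.items():
                io.write_response_matrix(R, outdir / f"responses_{ln}.tsv")
            io.write_viability_table(viability, outdir / "viability.tsv")
            topology = truth.edges()
            target_map = truth.target_map
            dose_levels = design.dose_levels
            _stage("synth")
        else:
            paths = config["responses"]  # {cell_line: path}
            responses = {
                ln: io.read_response_matrix(p, cell_line=ln) for ln, p in paths.items()
            }
            for ln, p in paths.items():
                manifest["inputs"][str(p)] = io.file_sha256(p)
            topology = io.read_prior_edges(config["prior"])
            map_cfg = io.load_config(config["drug_map"])
            target_map = map_cfg["targets"]
            dose_levels = map_cfg["dose_levels"]
            viability = None
            if config.get("viability"):
                viability = io.read_viability_table(config["viability"])
                manifest["inputs"][str(config["viability"])] = io.file_sha256(
                    config["viability"]
                )

        theta = config.get("theta", 2.0)
        theta = math.inf if theta in ("inf", None) else float(theta)
        result = final_model(
            responses,
            topology,
            theta=theta,
            drug_target_map=target_map,
            eta=float(config.get("eta", 0.1)),
        )
        io.save_cnr_result(result, outdir / "network.json")
        io.write_edge_list(result.r, outdir / "edges.tsv")
        artifacts["network"] = result
        _stage("reconstruct")

        if config.get("nulls"):
            ncfg = config["nulls"]
            ens = null_ensemble(
                responses,
                topology,
                target_map,
                mode=ncfg.get("mode", "random_topology"),
                n_models=int(ncfg.get("n_models", 100)),
                seed=seed,
                n_random_edges=ncfg.get("edges"),
                n_random_diffs=ncfg.get("diffs"),
            )
            (outdir / "nulls.json").write_text(
                json.dumps(
                    {
                        "mode": ens.mode,
                        "reference_rms": ens.reference_rms,
                        "rms_values": ens.rms_values.tolist(),
                        "p_value": empirical_pvalue(ens),
                        "seed": seed,
                    },
                    indent=1,
                )
            )
            artifacts["nulls"] = ens
            _stage("nulls")

        if viability is None:
            manifest["stopped"] = "no viability table configured; stopped after reconstruction"
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
            return artifacts

        form = config.get("viability_form", "4c")
        vfit = fit_viability_model(responses, viability, form=form)
        (outdir / "viability_fit.json").write_text(
            json.dumps(
                {
                    "form": vfit.form,
                    "params": vfit.params,
                    "sigma": vfit.sigma,
                    "loocv_l2": vfit.loocv_l2,
                },
                indent=1,
            )
        )
        artifacts["viability_fit"] = vfit
        _stage("fit-viability")

        dose_table = fit_dose_params(result.s_values, dose_levels, result.lines)
        dose_table.to_csv(outdir / "dose_params.tsv", sep="\t", index=False)
        artifacts["dose_params"] = dose_table
        _stage("dose-fit")

        by_line = dose_params_dict(dose_table)
        models = {}
        for ln in result.lines:
            prm = vfit.params_for(ln)
            models[ln] = CellLineModel(
                name=ln,
                r=result.r[ln],
                dose_params=by_line[ln],
                k_m_akt=prm["K_AKT"],
                k_m_erk=prm["K_ERK"],
                form=form,
            )
        caps = {d: dose_levels[d]["IC10"] for d in dose_levels}
        opt_cfg = OptimizerConfig(
            v_min=float(config.get("v_min", 0.8)), conc_cap=caps
        )
        floor = float(config.get("anti_selectivity_floor", 0.1))
        ranked, preds = rank_all_triples(
            models,
            direction=config.get("direction", "anti_selective"),
            config=opt_cfg,
            anti_selectivity_floor=floor,
        )
        ranked.to_csv(outdir / "ranked.tsv", sep="\t", index=False)
        artifacts["ranked"] = ranked
        _stage("optimize")

        controls = []
        for pred in preds:
            if not pred.success:
                continue
            ctrl = select_controls(models, pred.drugs, config=opt_cfg)
            controls.append(ctrl.anti_selectivity)
        selected = ranked.loc[ranked["passes_floor"], "score"].tolist()
        if selected and controls:
            power = power_analysis(
                selected,
                controls,
                noise_sd=float(config.get("power_noise_sd", 0.25)),
                n_sims=int(config.get("power_sims", 1000)),
                seed=seed,
            )
            (outdir / "power.json").write_text(
                json.dumps({"power": power, "n_selected": len(selected), "n_controls": len(controls)}, indent=1)
            )
            artifacts["power"] = power
            _stage("power")
        else:
            manifest["power_skipped"] = "no combinations passed the selectivity floor"
    except Exception as exc:
        stage = manifest["stages"][-1] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline failed after stage {stage!r}: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return artifacts
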