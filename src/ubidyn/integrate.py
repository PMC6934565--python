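"""Cross-modality integration and the batch pipeline driver.

Residue-resolved results from independent modalities — chemical-shift
perturbation, simulated surface burial (Delta-SASA), exchange-rate changes
(Delta k_HX) and R2/R1 mobility classes — are combined into an interface
report: each modality flags residues by its own significance rule, a
consensus interface is the set flagged by at least two modalities, and the
CSP/Delta-SASA agreement is quantified as a Pearson correlation over the
residues where both are defined.

``run_pipeline`` executes any subset of stages named in a JSON manifest in
dependency order, writes per-stage TSV outputs and records parameters,
package versions and the seed in a run manifest, so a run is reproducible
bit-for-bit from its inputs.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from pathlib import Path

import numpy as np

from . import io as uio
from .chemshift import CSPResult, csp
from .relaxometry import MobilityClass, classify_mobility, delta_khx, fit_decay_table, het_noe
from .types import ResidueSeries, RunConfig, ValidationError


def correlate(a: ResidueSeries, b: ResidueSeries) -> tuple[float, int]:
    """Pearson correlation over the residues present in both series.

    Returns (r, n_used); r is NaN when either side has zero variance
    (flagged by the caller as undefined rather than raised).
    """
    _keys, va, vb = a.aligned(b)
    n = len(va)
    if n < 5:
        raise ValidationError(f"need at least 5 shared residues, have {n}")
    if np.std(va) == 0.0 or np.std(vb) == 0.0:
        return float("nan"), n
    from scipy.stats import pearsonr

    r, _p = pearsonr(va, vb)
    return float(r), n


def spearman(a: ResidueSeries, b: ResidueSeries) -> tuple[float, int]:
    """Rank-based alternative to :func:`correlate`."""
    _keys, va, vb = a.aligned(b)
    n = len(va)
    if n < 5:
        raise ValidationError(f"need at least 5 shared residues, have {n}")
    from scipy.stats import spearmanr

    rho, _p = spearmanr(va, vb)
    return float(rho), n


def _mean_sd_flags(series: ResidueSeries, absolute: bool = False) -> set[int]:
    """Residues whose value exceeds the series mean + SD."""
    vals = np.array([series.values[k][0] for k in series])
    if absolute:
        vals = np.abs(vals)
    if len(vals) < 2:
        return set()
    thr = vals.mean() + vals.std(ddof=1)
    return {k.index for k, v in zip(series, vals) if v > thr}


@dataclasses.dataclass
class InterfaceReport:
    """Per-residue multi-modality table with the consensus interface set."""

    modality_flags: dict[str, set[int]]
    consensus: set[int]
    min_modalities: int
    correlation: tuple[float, int] | None
    table: dict[int, dict[str, float | str | None]]


def consensus_interface(
    csp_result: CSPResult | None = None,
    dsasa: ResidueSeries | None = None,
    dkhx: ResidueSeries | None = None,
    mobility: MobilityClass | None = None,
    min_modalities: int = 2,
) -> InterfaceReport:
    """Combine modality-specific significance calls into a consensus set.

    Rules: CSP — dw above mean + SD; Delta-SASA — above mean + SD;
    Delta k_HX — magnitude above mean + SD of magnitudes; mobility — any
    non-neutral R2/R1 class.  Consensus requires flags from at least
    ``min_modalities`` modalities.
    """
    flags: dict[str, set[int]] = {}
    if csp_result is not None:
        flags["csp"] = set(csp_result.strong)
    if dsasa is not None:
        flags["dsasa"] = _mean_sd_flags(dsasa)
    if dkhx is not None:
        flags["dkhx"] = _mean_sd_flags(dkhx, absolute=True)
    if mobility is not None:
        flags["mobility"] = mobility.slow | mobility.fast
    if len(flags) < 2:
        raise ValidationError("consensus needs at least two modalities")

    counts: dict[int, int] = {}
    for s in flags.values():
        for idx in s:
            counts[idx] = counts.get(idx, 0) + 1
    consensus = {idx for idx, c in counts.items() if c >= min_modalities}

    corr = None
    if csp_result is not None and dsasa is not None:
        try:
            corr = correlate(csp_result.delta_omega, dsasa)
        except ValidationError:
            corr = None

    table: dict[int, dict] = {}
    all_idx: set[int] = set()
    for s in flags.values():
        all_idx |= s
    sources: dict[str, ResidueSeries | None] = {
        "csp": csp_result.delta_omega if csp_result else None,
        "dsasa": dsasa,
        "dkhx": dkhx,
        "r2_r1": mobility.ratio if mobility else None,
    }
    for name, series in sources.items():
        if series is None:
            continue
        for key in series:
            all_idx.add(key.index)
    for idx in sorted(all_idx):
        row: dict[str, float | str | None] = {}
        for name, series in sources.items():
            if series is None:
                row[name] = None
            else:
                entry = series.by_index().get(idx)
                row[name] = entry[1][0] if entry else None
        if mobility is not None:
            row["mobility_class"] = (
                "slow" if idx in mobility.slow else "fast" if idx in mobility.fast else "neutral"
            )
        row["consensus"] = idx in consensus
        table[idx] = row
    return InterfaceReport(
        modality_flags=flags,
        consensus=consensus,
        min_modalities=min_modalities,
        correlation=corr,
        table=table,
    )


# --- pipeline driver ------------------------------------------------------

_STAGE_ORDER = [
    "csp", "mexico", "relax", "hetnoe", "diffusion",
    "titration", "dsasa", "rmsf", "gyrate", "cluster", "landscape",
    "consensus",
]


def _require(manifest_stage: dict, *keys: str) -> None:
    missing = [k for k in keys if k not in manifest_stage]
    if missing:
        raise ValidationError(f"stage input(s) missing: {missing}")


def _check_paths(manifest: dict) -> None:
    """Fail before any computation if a named input file is absent."""
    def walk(obj):
        if isinstance(obj, dict):
            for k, v in obj.items():
                if k in ("path", "peaks", "state_a", "state_b", "dimer", "monomer",
                         "ensemble", "curve", "sat", "unsat", "r1", "r2", "table"):
                    if isinstance(v, str) and not Path(v).exists():
                        raise ValidationError(f"input file not found: {v}")
                walk(v)
        elif isinstance(obj, list):
            for v in obj:
                walk(v)

    walk(manifest)


def run_pipeline(config: RunConfig, manifest: dict | str | Path, outdir: str | Path) -> dict:
    """Execute the stages named in ``manifest`` and write a report directory.

    Stages run in dependency order; outputs are TSV files plus a
    ``run_manifest.json`` with the configuration, seed and library
    versions.  Unknown stage names are an error, as is any missing input
    file (checked up front).  Returns a summary dict of what was produced.
    """
    if not isinstance(manifest, dict):
        with open(manifest) as fh:
            manifest = json.load(fh)
    unknown = set(manifest) - set(_STAGE_ORDER)
    if unknown:
        raise ValidationError(f"unknown stages: {sorted(unknown)}")
    _check_paths(manifest)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": {}}
    produced: dict = {}

    for stage in _STAGE_ORDER:
        if stage not in manifest:
            continue
        spec = manifest[stage]
        if stage == "csp":
            _require(spec, "state_a", "state_b")
            result = csp(
                uio.read_peaklist(spec["state_a"]),
                uio.read_peaklist(spec["state_b"]),
                attenuation_threshold=config.attenuation_threshold,
            )
            uio.write_series(result.delta_omega, outdir / "csp.tsv")
            produced["csp"] = result
            summary["stages"]["csp"] = {
                "mean": result.mean, "sd": result.sd,
                "significant": sorted(result.significant),
                "strong": sorted(result.strong),
                "attenuated": sorted(result.attenuated),
            }
        elif stage == "mexico":
            from .relaxometry import fit_mexico
            from .ubiquitin import UBIQUITIN_SEQUENCE
            from .types import ResidueKey

            _require(spec, "dimer", "monomer")
            r1w = spec.get("r1w", 0.31)
            rates = {}
            for name in ("dimer", "monomer"):
                curves = uio.read_decay_table(spec[name], kind="mexico")
                values = {}
                for idx, curve in sorted(curves.items()):
                    fit = fit_mexico(curve, r1w=r1w)
                    if fit.ok:
                        aa = UBIQUITIN_SEQUENCE[idx - 1] if idx <= len(UBIQUITIN_SEQUENCE) else "X"
                        err = fit.k_hx_err if np.isfinite(fit.k_hx_err) else 0.0
                        values[ResidueKey(idx, aa)] = (fit.k_hx, err)
                rates[name] = ResidueSeries(values=values, unit="1/s", metadata=f"k_HX {name}")
                uio.write_series(rates[name], outdir / f"khx_{name}.tsv")
            dk = delta_khx(rates["dimer"], rates["monomer"])
            uio.write_series(dk, outdir / "delta_khx.tsv")
            produced["dkhx"] = dk
            summary["stages"]["mexico"] = {"residues": len(dk)}
        elif stage == "relax":
            _require(spec, "r1", "r2")
            r1_series, _ = fit_decay_table(uio.read_decay_table(spec["r1"], kind="t1"))
            r2_series, _ = fit_decay_table(uio.read_decay_table(spec["r2"], kind="t2"))
            uio.write_series(r1_series, outdir / "r1.tsv")
            uio.write_series(r2_series, outdir / "r2.tsv")
            mob = classify_mobility(r1_series, r2_series, trim=config.trim_fraction)
            uio.write_series(mob.ratio, outdir / "r2_r1.tsv")
            produced["mobility"] = mob
            summary["stages"]["relax"] = {
                "trimmed_mean": mob.trimmed_mean, "trimmed_sd": mob.trimmed_sd,
                "slow": sorted(mob.slow), "fast": sorted(mob.fast),
                "exchange_suspect": sorted(mob.exchange_suspect),
            }
        elif stage == "hetnoe":
            _require(spec, "sat", "unsat")
            series, omitted = het_noe(
                uio.read_peaklist(spec["sat"]), uio.read_peaklist(spec["unsat"])
            )
            uio.write_series(series, outdir / "hetnoe.tsv")
            summary["stages"]["hetnoe"] = {"residues": len(series), "omitted": sorted(omitted)}
        elif stage == "diffusion":
            from .hydrodynamics import fit_diffusion
            from .models import GAMMA_1H

            _require(spec, "curve", "delta", "big_delta")
            curve = uio.read_decay_curve(spec["curve"], kind="diffusion")
            fit = fit_diffusion(
                curve,
                gamma=spec.get("gamma", GAMMA_1H),
                delta=spec["delta"],
                big_delta=spec["big_delta"],
            )
            summary["stages"]["diffusion"] = {
                "D_m2_per_s": fit.d, "D_err": fit.d_err, "flags": fit.flags,
            }
        elif stage == "titration":
            from .binding import TitrationSeries, fit_kd

            _require(spec, "points")
            points = [
                (uio.read_peaklist(p["peaks"]), float(p["p_total"]), float(p["l_total"]))
                for p in spec["points"]
            ]
            series = TitrationSeries(points=points, reference=spec.get("reference", 0))
            fit = fit_kd(
                series,
                mode=spec.get("mode", "per-residue"),
                n_fixed=spec.get("n", 1.0),
                attenuation_threshold=config.attenuation_threshold,
            )
            with open(outdir / "kd_per_residue.tsv", "w") as fh:
                fh.write("residue\tkd_uM\terror\n")
                for idx, (kd, err) in sorted(fit.per_residue.items()):
                    fh.write(f"{idx}\t{kd!r}\t{err!r}\n")
            summary["stages"]["titration"] = {
                "K_D_uM": fit.k_d, "K_D_err_uM": fit.k_d_err,
                "n": fit.n, "mode": fit.mode,
                "residues_used": sorted(fit.residues_used), "flags": fit.flags,
            }
        elif stage == "dsasa":
            from .ensembles import delta_sasa

            _require(spec, "dimer", "chain", "monomer")
            ds = delta_sasa(
                uio.read_ensemble(spec["dimer"]),
                spec["chain"],
                uio.read_ensemble(spec["monomer"]),
                probe=config.probe_radius,
                n_points=config.sphere_points,
            )
            uio.write_series(ds, outdir / "dsasa.tsv")
            produced["dsasa"] = ds
            summary["stages"]["dsasa"] = {"residues": len(ds)}
        elif stage == "rmsf":
            from .ensembles import BACKBONE_NAMES, rmsf

            _require(spec, "ensemble")
            ens = uio.read_ensemble(spec["ensemble"])
            sel = None
            if "chain" in spec:
                sel = ens.select(chain=spec["chain"], names=BACKBONE_NAMES)
            series = rmsf(ens, window=spec.get("window", config.rmsf_window), selection=sel)
            uio.write_series(series, outdir / "rmsf.tsv")
            summary["stages"]["rmsf"] = {"residues": len(series)}
        elif stage == "gyrate":
            from .ensembles import gyration

            _require(spec, "ensemble")
            res = gyration(uio.read_ensemble(spec["ensemble"]))
            summary["stages"]["gyrate"] = {"mean_A": res.mean, "sd_A": res.sd}
        elif stage == "cluster":
            from .ensembles import rmsd_cluster

            _require(spec, "ensemble")
            ens = uio.read_ensemble(spec["ensemble"])
            result = rmsd_cluster(
                ens, k=spec.get("k", config.n_clusters), stride=spec.get("stride", 1)
            )
            np.savetxt(outdir / "rmsd_matrix.txt", result.rmsd_matrix, fmt="%.6f")
            summary["stages"]["cluster"] = {
                "k": result.k,
                "populations": {str(k): v for k, v in sorted(result.populations.items())},
                "centroids": {str(k): v for k, v in sorted(result.centroids.items())},
                "top3_population": result.most_populated(3),
            }
        elif stage == "landscape":
            from .ensembles import landscape as make_landscape
            from .ensembles import min_distance_cvs

            _require(spec, "ensemble")
            ens = uio.read_ensemble(spec["ensemble"])
            core = tuple(spec.get("core", (1, 72)))
            cvs = min_distance_cvs(ens, core=core, atom_name=spec.get("atom_name", "CA"))
            np.savetxt(outdir / "cvs.txt", cvs, fmt="%.6f")
            land = make_landscape(
                cvs, bins=config.landscape_bins, temperature=config.temperature
            )
            np.savetxt(outdir / "free_energy.tsv", land.free_energy, fmt="%.6f", delimiter="\t")
            summary["stages"]["landscape"] = {
                "bins": config.landscape_bins,
                "minima": land.minima[:5],
            }
        elif stage == "consensus":
            report = consensus_interface(
                csp_result=produced.get("csp"),
                dsasa=produced.get("dsasa"),
                dkhx=produced.get("dkhx"),
                mobility=produced.get("mobility"),
                min_modalities=spec.get("min_modalities", 2) if isinstance(spec, dict) else 2,
            )
            with open(outdir / "consensus.tsv", "w") as fh:
                cols = ["residue", "csp", "dsasa", "dkhx", "r2_r1", "consensus"]
                fh.write("\t".join(cols) + "\n")
                for idx, row in sorted(report.table.items()):
                    vals = [str(idx)] + [
                        "" if row.get(c) is None else str(row.get(c)) for c in cols[1:]
                    ]
                    fh.write("\t".join(vals) + "\n")
            summary["stages"]["consensus"] = {
                "consensus": sorted(report.consensus),
                "flags": {k: sorted(v) for k, v in report.modality_flags.items()},
                "csp_dsasa_pearson_r": report.correlation,
            }

    import ubidyn

    summary["run"] = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "versions": {
            "ubidyn": ubidyn.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=str)
    return summary
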