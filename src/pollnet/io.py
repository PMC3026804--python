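"""File formats, configuration and the end-to-end analysis pipeline.

Canonical on-disk formats: CSV for tabular inputs/outputs (comma, UTF-8,
header row, ``#`` provenance/comment lines), Pajek ``.net`` and GraphML for
graphs, JSON for machine-readable reports.  ``run_pipeline`` chains
filter -> incidence -> projections -> metrics -> null models -> diversity ->
residualization -> spatial regression / partial Mantel, writing a
deterministic report bundle.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .construction import (
    ProjectionGraph,
    build_incidence,
    filter_plants,
    project_plants,
    project_pollinators,
    validate_visitation,
)
from .diversity import (
    dissimilarity_matrix,
    fit_sar_mix,
    hurlbert_pie,
    one_way_anova,
    partial_mantel,
    residualize,
    spatial_weights,
)
from .metrics import (
    group_functional_specialization,
    group_hub_degree,
    metrics_report,
)
from .nulls import nodf_null_test, random_visitation_ensemble

__all__ = [
    "StudyConfig",
    "read_visitation",
    "read_plants",
    "read_populations",
    "write_visitation",
    "write_pajek",
    "read_pajek",
    "write_graphml",
    "run_pipeline",
]

PLANT_COLUMNS = ("population_id", "plant_id", "x_m", "y_m", "flowers", "juveniles")
POPULATION_COLUMNS = ("population_id", "x_km", "y_km")


# ---------------------------------------------------------------------------
# configuration


@dataclass
class StudyConfig:
    """Paths, thresholds and seeds driving one pipeline run."""

    visits_path: str
    plants_path: str
    populations_path: str
    out_dir: str
    min_minutes: float = 15.0
    nodf_reps: int = 1000
    null_reps: int = 1000
    master_rows: int = 100_000
    mantel_permutations: int = 1000
    sar_scheme: str = "inverse_distance"
    seed: int = 0
    run_nulls: bool = True
    export_networks: bool = True

    def digest(self) -> str:
        # out_dir is excluded: it locates the bundle but does not alter it
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _provenance(config: StudyConfig) -> str:
    return f"pollnet v{__version__} config={config.digest()} seed={config.seed}"


# ---------------------------------------------------------------------------
# tabular readers / writers


def _read_csv(path: str | Path, required: tuple, label: str) -> pd.DataFrame:
    table = pd.read_csv(path, comment="#")
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(
            f"{label} table at {path} is missing columns {missing}; "
            f"expected header: {list(required)}"
        )
    return table


def read_visitation(path: str | Path) -> pd.DataFrame:
    """Read and schema-validate a visitation CSV."""
    return validate_visitation(pd.read_csv(path, comment="#"))


def read_plants(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, PLANT_COLUMNS, "plants")


def read_populations(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, POPULATION_COLUMNS, "populations")


def write_visitation(table: pd.DataFrame, path: str | Path) -> None:
    validate_visitation(table).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# graph formats


def write_pajek(
    graph: ProjectionGraph, path: str | Path, weighted_lines: bool = False
) -> None:
    """Write a multigraph as Pajek ``.net``.

    By default each shared partner becomes its own edge line (multiple lines);
    with ``weighted_lines=True`` a single line per pair carries the
    multiplicity as its weight.
    """
    lines = [f"*Vertices {graph.n}"]
    for i, node in enumerate(graph.nodes, start=1):
        lines.append(f'{i} "{node}"')
    lines.append("*Edges")
    iu, ju = np.nonzero(np.triu(graph.multiplicity, k=1))
    for i, j in zip(iu, ju):
        m = int(graph.multiplicity[i, j])
        if weighted_lines:
            lines.append(f"{i + 1} {j + 1} {m}")
        else:
            lines.extend([f"{i + 1} {j + 1} 1"] * m)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_pajek(path: str | Path) -> ProjectionGraph:
    """Parse a Pajek ``.net`` file written by :func:`write_pajek`."""
    text = Path(path).read_text(encoding="utf-8").splitlines()
    it = iter(text)
    header = next(it)
    if not header.lower().startswith("*vertices"):
        raise ValueError("not a Pajek file: missing *Vertices header")
    n = int(header.split()[1])
    nodes = [None] * n
    for _ in range(n):
        line = next(it)
        idx, label = line.split(maxsplit=1)
        nodes[int(idx) - 1] = label.strip().strip('"')
    marker = next(it)
    if not marker.lower().startswith(("*edges", "*arcs")):
        raise ValueError("missing *Edges section")
    mult = np.zeros((n, n), dtype=np.int64)
    for line in it:
        if not line.strip():
            continue
        parts = line.split()
        i, j = int(parts[0]) - 1, int(parts[1]) - 1
        w = int(float(parts[2])) if len(parts) > 2 else 1
        mult[i, j] += w
        mult[j, i] += w
    return ProjectionGraph(nodes=nodes, multiplicity=mult)


def write_graphml(graph: ProjectionGraph, path: str | Path) -> None:
    """Export the simple reduction with multiplicity as an edge attribute."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    iu, ju = np.nonzero(np.triu(graph.multiplicity, k=1))
    for i, j in zip(iu, ju):
        g.add_edge(
            graph.nodes[i], graph.nodes[j], multiplicity=int(graph.multiplicity[i, j])
        )
    nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# pipeline


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _per_population_analysis(
    visits: pd.DataFrame, config: StudyConfig, log: list
) -> tuple[pd.DataFrame, dict, dict]:
    """Filter, build, measure and null-test each population's network."""
    rows = []
    nulls_out: dict = {}
    graphs: dict = {}
    ss = np.random.SeedSequence(config.seed)
    pop_ids = sorted(visits["population_id"].unique())
    children = ss.spawn(len(pop_ids))
    for pid, child in zip(pop_ids, children):
        sub = visits[visits["population_id"] == pid]
        filtered, report = filter_plants(
            sub, min_minutes=config.min_minutes, return_report=True
        )
        log.append(f"[{pid}] filter: {report}")
        inc = build_incidence(filtered)
        g = project_plants(inc)
        pg = project_pollinators(inc)
        graphs[pid] = {"plants": g, "pollinators": pg, "incidence": inc}
        rep = metrics_report(inc, g)
        row = {"population_id": pid, **rep.to_dict()}
        if config.run_nulls:
            rngs = child.spawn(2)
            seed_nodf = int(np.random.default_rng(rngs[0]).integers(2**31))
            seed_rand = int(np.random.default_rng(rngs[1]).integers(2**31))
            ens, rel = nodf_null_test(
                inc.presence, reps=config.nodf_reps, seed=seed_nodf
            )
            row["relative_nestedness"] = rel
            row["nodf_p"] = ens.p_value
            rand = random_visitation_ensemble(
                inc,
                reps=config.null_reps,
                master_rows=config.master_rows,
                seed=seed_rand,
            )
            for name, e in rand.items():
                row[f"{name}_p"] = e.p_value
            nulls_out[pid] = {
                "nodf": ens.to_dict(),
                **{name: e.to_dict() for name, e in rand.items()},
            }
            log.append(
                f"[{pid}] nulls: nodf p={ens.p_value:.4g}, "
                + ", ".join(f"{n} p={e.p_value:.4g}" for n, e in rand.items())
            )
        rows.append(row)
        log.append(
            f"[{pid}] metrics: n={rep.n_plants}, pol={rep.n_pollinators}, "
            f"NODF={rep.nodf:.2f}, conn={rep.connectance:.3f}, "
            f"clus={rep.clustering_mean:.3f}"
        )
    return pd.DataFrame(rows), nulls_out, graphs


def _assemblage_summaries(visits: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray, list]:
    """Per-population abundance/richness/PIE plus an aligned count matrix."""
    real = visits[visits["visits"] >= 1]
    pop_ids = sorted(visits["population_id"].unique())
    species = sorted(real["pollinator_species"].unique())
    counts = np.zeros((len(pop_ids), len(species)))
    s_index = {s: k for k, s in enumerate(species)}
    for p, pid in enumerate(pop_ids):
        sub = real[real["population_id"] == pid]
        for sp, v in sub.groupby("pollinator_species")["visits"].sum().items():
            counts[p, s_index[sp]] = v
    rows = [
        {
            "population_id": pid,
            "abundance": float(counts[p].sum()),
            "s_obs": int((counts[p] > 0).sum()),
            "hurlbert_pie": hurlbert_pie(counts[p]) if counts[p].sum() >= 2 else np.nan,
        }
        for p, pid in enumerate(pop_ids)
    ]
    return pd.DataFrame(rows), counts, pop_ids


def _pollinator_group_metrics(graphs: dict, log: list) -> pd.DataFrame:
    """Per population x functional group hub degree and FS (for the ANOVA)."""
    rows = []
    for pid, bundle in sorted(graphs.items()):
        pg = bundle["pollinators"]
        groups = sorted({g for g in pg.node_groups.values() if g is not None})
        for grp in groups:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    hub = group_hub_degree(pg, grp)
                    fs = group_functional_specialization(pg, grp)
            except (ValueError, RuntimeError) as exc:
                log.append(f"[{pid}] group {grp}: skipped ({exc})")
                continue
            rows.append(
                {
                    "population_id": pid,
                    "functional_group": grp,
                    "hub_degree": hub,
                    "functional_specialization": fs,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: StudyConfig, tables: dict | None = None) -> dict:
    """Execute the full analysis chain and write the report bundle.

    Returns a dict with the per-population metric table, fitted statistics and
    paths of everything written.  Deterministic for a fixed config (seeds are
    derived from ``config.seed``; no timestamps are embedded).  Input tables
    may be supplied in memory via ``tables`` (keys ``visits``, ``plants``,
    ``populations``), bypassing the configured paths.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [_provenance(config)]
    results: dict = {}

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, str(exc)) from exc

        return wrap

    if tables is not None:
        visits = stage("read_visitation")(validate_visitation, tables["visits"])
        plants = tables["plants"]
        pops = tables["populations"]
    else:
        visits = stage("read_visitation")(read_visitation, config.visits_path)
        plants = stage("read_plants")(read_plants, config.plants_path)
        pops = stage("read_populations")(read_populations, config.populations_path)
    log.append(
        f"inputs: {len(visits)} visitation rows, {len(plants)} plants, "
        f"{len(pops)} populations"
    )

    table1, nulls_out, graphs = stage("networks")(
        _per_population_analysis, visits, config, log
    )
    assemblage, count_matrix, pop_ids = stage("diversity")(
        _assemblage_summaries, visits
    )
    table1 = table1.merge(assemblage, on="population_id")

    if config.export_networks:
        netdir = out / "networks"
        netdir.mkdir(exist_ok=True)
        for pid, bundle in graphs.items():
            write_pajek(bundle["plants"], netdir / f"{pid}_plants.net")
            write_graphml(bundle["plants"], netdir / f"{pid}_plants.graphml")

    # ---- performance + spatial statistics (needs >= 4 populations) --------
    n_pops = len(pop_ids)
    pops = pops.sort_values("population_id").reset_index(drop=True)
    if list(pops["population_id"]) != pop_ids:
        raise PipelineStageError(
            "spatial", "population table does not match visitation populations"
        )
    coords = pops[["x_km", "y_km"]].to_numpy(dtype=float)

    perf = (
        plants.groupby("population_id")["juveniles"].mean().reindex(pop_ids)
    )
    table1["per_capita_juveniles"] = perf.to_numpy()

    sar_results: dict = {}
    table2_rows: list[dict] = []
    anova_out: dict = {}
    if n_pops >= 4:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sw = spatial_weights(coords, scheme=config.sar_scheme)

            abundance = table1["abundance"].to_numpy(dtype=float)
            richness = table1["s_obs"].to_numpy(dtype=float)
            metric_cols = {
                "nodf": table1["nodf"].to_numpy(dtype=float),
                "normalized_degree": table1["normalized_degree_mean"].to_numpy(float),
                "connectance": table1["connectance"].to_numpy(dtype=float),
                "clustering": table1["clustering_mean"].to_numpy(dtype=float),
            }
            # residual metrics per the abundance/richness controls
            resid_metrics = {
                "nodf": metric_cols["nodf"],
                "normalized_degree": residualize(
                    metric_cols["normalized_degree"], abundance
                ),
                "connectance": residualize(metric_cols["connectance"], abundance),
                "clustering": residualize(metric_cols["clustering"], richness),
            }

            y = perf.to_numpy(dtype=float)
            for name, x in resid_metrics.items():
                try:
                    fit = fit_sar_mix(y, x[:, None], sw, predictor_names=[name])
                    sar_results[name] = fit.summary()
                    log.append(
                        f"performance ~ {name}: slope="
                        f"{fit.summary()['coefficients'][name]['estimate']:.4g} "
                        f"(p={fit.summary()['coefficients'][name]['p']:.3g})"
                    )
                except (ValueError, np.linalg.LinAlgError) as exc:
                    log.append(f"performance ~ {name}: SAR failed ({exc})")

            # predictor grid: assemblage descriptors vs raw metrics
            geo = np.sqrt(
                ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
            )
            bc = dissimilarity_matrix(count_matrix, "bray_curtis")
            mh = dissimilarity_matrix(count_matrix, "morisita_horn")
            pie = table1["hurlbert_pie"].to_numpy(dtype=float)
            mantel_seed = int(
                np.random.default_rng(
                    np.random.SeedSequence(config.seed).spawn(1)[0]
                ).integers(2**31)
            )
            for mname, mvals in metric_cols.items():
                row = {"metric": mname}
                for pname, pvals in (
                    ("abundance", abundance),
                    ("s_obs", richness),
                    ("hurlbert_pie", pie),
                ):
                    try:
                        fit = fit_sar_mix(
                            mvals, pvals[:, None], sw, predictor_names=[pname]
                        )
                        c = fit.summary()["coefficients"][pname]
                        row[f"{pname}_coef"] = c["estimate"]
                        row[f"{pname}_se"] = c["se"]
                        row[f"{pname}_p"] = c["p"]
                    except (ValueError, np.linalg.LinAlgError):
                        row[f"{pname}_coef"] = np.nan
                for dname, dmat in (("bray_curtis", bc), ("morisita_horn", mh)):
                    md = np.abs(mvals[:, None] - mvals[None, :])
                    res = partial_mantel(
                        md,
                        dmat,
                        geo,
                        permutations=config.mantel_permutations,
                        seed=mantel_seed,
                    )
                    row[f"{dname}_r"] = res.statistic
                    row[f"{dname}_p"] = res.p_value
                table2_rows.append(row)

            group_metrics = _pollinator_group_metrics(graphs, log)
            if not group_metrics.empty:
                counts_per_group = group_metrics["functional_group"].value_counts()
                usable = counts_per_group[counts_per_group >= 2].index
                gm = group_metrics[group_metrics["functional_group"].isin(usable)]
                for col in ("hub_degree", "functional_specialization"):
                    vals = gm[col].to_numpy(dtype=float)
                    ok = np.isfinite(vals)
                    if ok.sum() >= 4 and gm["functional_group"][ok].nunique() >= 2:
                        try:
                            anova_out[col] = one_way_anova(
                                vals[ok], gm["functional_group"].to_numpy()[ok]
                            )
                        except ValueError as exc:
                            log.append(f"anova {col}: skipped ({exc})")
                group_metrics.to_csv(
                    out / "group_metrics.csv", index=False, float_format="%.6g"
                )
    else:
        log.append("fewer than 4 populations: spatial statistics skipped")

    # ---- write bundle -----------------------------------------------------
    prov = "# " + _provenance(config) + "\n"

    def write_csv(df: pd.DataFrame, name: str) -> Path:
        path = out / name
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(prov)
            df.to_csv(fh, index=False, float_format="%.6g", lineterminator="\n")
        return path

    write_csv(table1, "table1.csv")
    if table2_rows:
        write_csv(pd.DataFrame(table2_rows), "table2.csv")

    report = {
        "_provenance": _provenance(config),
        "null_tests": nulls_out,
        "performance_sar": sar_results,
        "anova": anova_out,
    }
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=float) + "\n",
        encoding="utf-8",
    )
    (out / "pipeline.log").write_text("\n".join(log) + "\n", encoding="utf-8")

    results.update(
        {
            "table1": table1,
            "table2": pd.DataFrame(table2_rows) if table2_rows else None,
            "performance_sar": sar_results,
            "anova": anova_out,
            "null_tests": nulls_out,
            "out_dir": str(out),
            "log": log,
        }
    )
    return results
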