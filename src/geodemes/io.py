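"""On-disk formats: table TSVs, model bundles, VCF and EIGENSTRAT export.

Every writer is deterministic given its input: stable row ordering and
fixed float formatting, so identical simulations serialize to identical
bytes.  Genome coordinates inside table TSVs use shortest-round-trip
(``repr``) formatting to survive a save/load cycle exactly; user-facing
exports round to six significant digits.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
import shapely

from . import demography as dem
from .demography import CompiledModel, SpatialParams, PopulationConfig, SamplingEvent
from .landscape import Point, Region, World, make_world
from .stats import genotype_matrix
from .tables import GenealogyTables

__all__ = [
    "write_tables",
    "load_tables",
    "write_bundle",
    "load_bundle",
    "model_digest",
    "write_vcf",
    "write_eigenstrat",
]


def _f(x: float) -> str:
    """Exact (round-trip) float formatting."""
    return repr(float(x))


# ---------------------------------------------------------------------------
# genealogy tables
# ---------------------------------------------------------------------------

def write_tables(tables: GenealogyTables, path, seed: Optional[int] = None,
                 model: Optional[CompiledModel] = None) -> None:
    """Serialize tables to four TSVs plus a manifest in ``path``.

    Sites and mutations share one file (``mutations.tsv``) since the
    infinite-sites model pairs them one to one.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    with open(path / "nodes.tsv", "w") as fh:
        fh.write("node_id\tbirth_gen\tpopulation\tindividual\tis_sample\n")
        for i in range(tables.num_nodes):
            fh.write(
                f"{i}\t{tables.node_birth_gen[i]}\t{tables.node_population[i]}\t"
                f"{tables.node_individual[i]}\t{int(tables.node_is_sample[i])}\n"
            )
    with open(path / "individuals.tsv", "w") as fh:
        fh.write("individual_id\tname\tpopulation\tbirth_gen\tx\ty\n")
        for i in range(tables.num_individuals):
            name = tables.indiv_names.get(i, "")
            fh.write(
                f"{i}\t{name}\t{tables.indiv_population[i]}\t"
                f"{tables.indiv_birth_gen[i]}\t{_f(tables.indiv_x[i])}\t"
                f"{_f(tables.indiv_y[i])}\n"
            )
    with open(path / "edges.tsv", "w") as fh:
        fh.write("left\tright\tparent\tchild\n")
        for i in range(tables.num_edges):
            fh.write(
                f"{_f(tables.edges_left[i])}\t{_f(tables.edges_right[i])}\t"
                f"{tables.edges_parent[i]}\t{tables.edges_child[i]}\n"
            )
    with open(path / "mutations.tsv", "w") as fh:
        fh.write("site\tposition\tancestral\tderived\tnode\n")
        for i in range(tables.num_sites):
            fh.write(f"{i}\t{tables.sites_position[i]}\tA\tT\t{tables.mut_node[i]}\n")

    manifest = {
        "format": "geodemes-tables",
        "sequence_length": float(tables.sequence_length),
        "population_names": list(tables.population_names),
    }
    if seed is not None:
        manifest["seed"] = int(seed)
    if model is not None:
        manifest["time_units"] = {
            "direction": model.direction,
            "generation_time": model.generation_time,
            "oldest_time": model.T0,
        }
    with open(path / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def load_tables(path) -> GenealogyTables:
    path = Path(path)
    with open(path / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    nodes = pd.read_csv(path / "nodes.tsv", sep="\t")
    indiv = pd.read_csv(path / "individuals.tsv", sep="\t",
                        keep_default_na=False, na_values=[],
                        float_precision="round_trip")
    edges = pd.read_csv(path / "edges.tsv", sep="\t",
                        float_precision="round_trip")
    muts = pd.read_csv(path / "mutations.tsv", sep="\t")
    names = {
        int(r.individual_id): str(r.name)
        for r in indiv.itertuples()
        if str(r.name) != ""
    }
    return GenealogyTables(
        sequence_length=float(manifest["sequence_length"]),
        node_birth_gen=nodes["birth_gen"].to_numpy(np.int64),
        node_population=nodes["population"].to_numpy(np.int32),
        node_individual=nodes["individual"].to_numpy(np.int64),
        node_is_sample=nodes["is_sample"].to_numpy(bool),
        indiv_population=indiv["population"].to_numpy(np.int32),
        indiv_birth_gen=indiv["birth_gen"].to_numpy(np.int64),
        indiv_x=indiv["x"].astype(float).to_numpy(),
        indiv_y=indiv["y"].astype(float).to_numpy(),
        indiv_names=names,
        edges_left=edges["left"].to_numpy(float),
        edges_right=edges["right"].to_numpy(float),
        edges_parent=edges["parent"].to_numpy(np.int64),
        edges_child=edges["child"].to_numpy(np.int64),
        sites_position=muts["position"].to_numpy(np.int64),
        mut_site=muts["site"].to_numpy(np.int64),
        mut_node=muts["node"].to_numpy(np.int64),
        population_names=list(manifest.get("population_names", [])),
    )


# ---------------------------------------------------------------------------
# model bundles
# ---------------------------------------------------------------------------

def _spatial_fields(sp: Optional[SpatialParams]) -> list[str]:
    if sp is None:
        return ["", "", "", ""]
    return [
        "" if sp.competition is None else _f(sp.competition),
        "" if sp.mating is None else _f(sp.mating),
        "" if sp.dispersal is None else _f(sp.dispersal),
        "" if sp.dispersal_fun is None else sp.dispersal_fun,
    ]


def _opt_float(s: str) -> Optional[float]:
    return None if s == "" else float(s)


def write_bundle(model: CompiledModel, path) -> None:
    """Write a self-contained bundle directory for the compiled model.

    The bundle holds the declarative configuration (populations, events,
    sampling, initial ranges) plus the compiled per-generation range
    snapshots (``ranges/{pop}_{gen}.wkt``); loading re-runs compilation,
    which is pure, so a load/save cycle is byte-stable.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "ranges").mkdir(exist_ok=True)

    lines = ["name\tstart_time\tN\tparent\tremoval_time\tcompetition\tmating\t"
             "dispersal\tdispersal_fun\thas_range"]
    for p in model.config_populations:
        sp = _spatial_fields(p.spatial)
        lines.append("\t".join([
            p.name, _f(p.start_time), str(p.N),
            p.parent or "", "" if p.removal_time is None else _f(p.removal_time),
            *sp, "1" if p.initial_range is not None else "0",
        ]))
    (path / "populations.tsv").write_text("\n".join(lines) + "\n")

    lines = ["type\tpop\tsource\ttarget\ttime\tstart\tend\tN_new\thow\tby\trate\t"
             "require_overlap\twaypoints\tcompetition\tmating\tdispersal\tdispersal_fun"]
    for ev in model.config_events:
        row = {k: "" for k in ("type", "pop", "source", "target", "time", "start",
                               "end", "N_new", "how", "by", "rate",
                               "require_overlap", "waypoints", "competition",
                               "mating", "dispersal", "dispersal_fun")}
        if isinstance(ev, dem.Resize):
            row.update(type="resize", pop=ev.pop, time=_f(ev.time),
                       N_new=str(ev.N_new), how=ev.how,
                       end=_f(ev.end_time) if ev.end_time is not None else "")
        elif isinstance(ev, dem.Move):
            row.update(type="move", pop=ev.pop, start=_f(ev.start), end=_f(ev.end),
                       waypoints=";".join(f"{_f(w[0])},{_f(w[1])}"
                                          for w in ev.waypoints))
        elif isinstance(ev, dem.Expand):
            row.update(type="expand", pop=ev.pop, start=_f(ev.start),
                       end=_f(ev.end), by=_f(ev.by))
        elif isinstance(ev, dem.DispersalChange):
            c, m, d, f = _spatial_fields(ev.params)
            row.update(type="dispersal", pop=ev.pop, time=_f(ev.time),
                       competition=c, mating=m, dispersal=d, dispersal_fun=f)
        elif isinstance(ev, dem.GeneFlow):
            row.update(type="gene_flow", source=ev.source, target=ev.target,
                       rate=_f(ev.rate), start=_f(ev.start), end=_f(ev.end),
                       require_overlap=str(int(ev.require_overlap)))
        lines.append("\t".join(row[k] for k in (
            "type", "pop", "source", "target", "time", "start", "end", "N_new",
            "how", "by", "rate", "require_overlap", "waypoints", "competition",
            "mating", "dispersal", "dispersal_fun")))
    (path / "events.tsv").write_text("\n".join(lines) + "\n")

    lines = ["time\tpop\tn\tx\ty"]
    for s in model.config_sampling:
        x = _f(s.location[0]) if s.location is not None else ""
        y = _f(s.location[1]) if s.location is not None else ""
        lines.append(f"{_f(s.time)}\t{s.pop}\t{s.n}\t{x}\t{y}")
    (path / "sampling.tsv").write_text("\n".join(lines) + "\n")

    # declared initial ranges ({pop}_{start_gen}.wkt) and compiled snapshots
    range_files: list[Path] = []
    for p in model.config_populations:
        if p.initial_range is None:
            continue
        cp = model.pop(p.name)
        f = path / "ranges" / f"{p.name}_{cp.start_gen}.wkt"
        f.write_text(f"{p.name}\t{p.initial_range.to_wkt()}\n")
        range_files.append(f)
    for cp in model.populations:
        for gen, region in cp.ranges:
            f = path / "ranges" / f"{cp.name}_{gen}.wkt"
            if f in range_files:
                continue  # keep the declared initial range, not the clipped one
            if not f.exists():
                f.write_text(f"{cp.name}\t{region.to_wkt()}\n")

    digest = hashlib.sha256()
    for fname in ("populations.tsv", "events.tsv", "sampling.tsv"):
        digest.update((path / fname).read_bytes())
    for f in sorted((path / "ranges").glob("*.wkt")):
        digest.update(f.name.encode())
        digest.update(f.read_bytes())

    manifest: dict = {
        "format": "geodemes-bundle",
        "name": model.name,
        "direction": model.direction,
        "generation_time": model.generation_time,
        "end_time": model.T1,
        "generations": model.G,
        "hash": digest.hexdigest(),
    }
    if model.world is not None:
        manifest["world"] = {
            "extent": [float(v) for v in model.world.extent],
            "habitable": [
                {"name": r.name, "wkt": r.to_wkt()} for r in model.world.habitable
            ],
        }
    with open(path / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def load_bundle(path) -> CompiledModel:
    """Reconstruct and re-compile the model stored in a bundle directory."""
    path = Path(path)
    with open(path / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    if manifest.get("format") != "geodemes-bundle":
        raise ValueError(f"{path} is not a geodemes model bundle")

    world = None
    if "world" in manifest:
        habitable = [
            Region(h["name"], shapely.from_wkt(h["wkt"]))
            for h in manifest["world"]["habitable"]
        ]
        world = make_world(tuple(manifest["world"]["extent"]), habitable)

    pops_df = pd.read_csv(path / "populations.tsv", sep="\t",
                          keep_default_na=False, na_values=[], dtype=str)
    g = float(manifest["generation_time"])
    direction = manifest["direction"]

    populations = []
    for r in pops_df.itertuples():
        sp = None
        if any(v != "" for v in (r.competition, r.mating, r.dispersal, r.dispersal_fun)):
            sp = SpatialParams(
                _opt_float(r.competition), _opt_float(r.mating),
                _opt_float(r.dispersal), r.dispersal_fun or None,
            )
        initial_range = None
        if r.has_range == "1":
            # the file at the population's start generation holds the
            # declared (unclipped) range
            start_gen = dem._to_gen(float(r.start_time),
                                    _oldest_time(manifest, pops_df, path),
                                    g, direction)
            f = path / "ranges" / f"{r.name}_{start_gen}.wkt"
            nm, wkt = f.read_text().strip().split("\t", 1)
            initial_range = Region(nm, shapely.from_wkt(wkt))
        populations.append(PopulationConfig(
            name=r.name, start_time=float(r.start_time), N=int(r.N),
            parent=r.parent or None, initial_range=initial_range, spatial=sp,
            removal_time=_opt_float(r.removal_time),
        ))

    events = []
    ev_df = pd.read_csv(path / "events.tsv", sep="\t",
                        keep_default_na=False, na_values=[], dtype=str)
    for r in ev_df.itertuples():
        if r.type == "resize":
            events.append(dem.Resize(r.pop, float(r.time), int(r.N_new), r.how,
                                     _opt_float(r.end)))
        elif r.type == "move":
            wps = tuple(
                Point(*(float(v) for v in w.split(",")))
                for w in r.waypoints.split(";")
            )
            events.append(dem.Move(r.pop, float(r.start), float(r.end), wps))
        elif r.type == "expand":
            events.append(dem.Expand(r.pop, float(r.start), float(r.end),
                                     float(r.by)))
        elif r.type == "dispersal":
            events.append(dem.DispersalChange(r.pop, float(r.time), SpatialParams(
                _opt_float(r.competition), _opt_float(r.mating),
                _opt_float(r.dispersal), r.dispersal_fun or None)))
        elif r.type == "gene_flow":
            events.append(dem.GeneFlow(r.source, r.target, float(r.rate),
                                       float(r.start), float(r.end),
                                       bool(int(r.require_overlap))))
        else:
            raise ValueError(f"unknown event type {r.type!r} in bundle")

    sampling = []
    s_df = pd.read_csv(path / "sampling.tsv", sep="\t",
                       keep_default_na=False, na_values=[], dtype=str)
    for r in s_df.itertuples():
        loc = Point(float(r.x), float(r.y)) if r.x != "" else None
        sampling.append(SamplingEvent(float(r.time), r.pop, int(r.n), loc))

    return dem.compile_model(
        populations=populations, events=events, sampling=sampling,
        generation_time=g, direction=direction, world=world,
        end_time=float(manifest["end_time"]), name=manifest.get("name", "model"),
    )


def _oldest_time(manifest, pops_df, path) -> float:
    times = [float(t) for t in pops_df["start_time"]]
    times += [float(v) for v in pops_df["removal_time"] if v != ""]
    ev_df = pd.read_csv(path / "events.tsv", sep="\t",
                        keep_default_na=False, na_values=[], dtype=str)
    for col in ("time", "start", "end"):
        times += [float(v) for v in ev_df[col] if v != ""]
    s_df = pd.read_csv(path / "sampling.tsv", sep="\t",
                       keep_default_na=False, na_values=[], dtype=str)
    times += [float(v) for v in s_df["time"]]
    times.append(float(manifest["end_time"]))
    return min(times) if manifest["direction"] == "forward" else max(times)


def model_digest(model: CompiledModel, tmpdir=None) -> str:
    """Hash of the model's canonical bundle serialization (seed-independent)."""
    import tempfile

    with tempfile.TemporaryDirectory(dir=tmpdir) as d:
        write_bundle(model, d)
        with open(Path(d) / "manifest.yaml") as fh:
            return yaml.safe_load(fh)["hash"]


# ---------------------------------------------------------------------------
# genotype exports
# ---------------------------------------------------------------------------

def _sampled_individuals(tables: GenealogyTables) -> tuple[list[int], np.ndarray]:
    """Sampled individual ids (sorted) and their 2 x n sample-node matrix."""
    ids = sorted(tables.indiv_names)
    node_rows = []
    for i in ids:
        nodes = np.flatnonzero(
            (tables.node_individual == i) & tables.node_is_sample
        )
        if len(nodes) != 2:
            raise ValueError(
                f"individual {tables.indiv_names[i]!r} has {len(nodes)} sample "
                f"nodes; diploid export requires exactly 2"
            )
        node_rows.append(nodes)
    return ids, (np.array(node_rows, dtype=np.int64)
                 if node_rows else np.empty((0, 2), np.int64))


def write_vcf(tables: GenealogyTables, path) -> None:
    """Write a VCFv4.2 with one phased diploid genotype column per individual."""
    ids, node_pairs = _sampled_individuals(tables)
    names = [tables.indiv_names[i] for i in ids]
    order = np.argsort(tables.sites_position, kind="stable")
    geno = genotype_matrix(tables, node_pairs.reshape(-1))  # sites x 2n
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=geodemes\n")
        fh.write(f"##contig=<ID=1,length={int(tables.sequence_length)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(names) + "\n")
        for s in order:
            pos = int(tables.sites_position[s]) + 1
            gts = "\t".join(
                f"{geno[s, 2 * k]}|{geno[s, 2 * k + 1]}" for k in range(len(ids))
            )
            fh.write(f"1\t{pos}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def write_eigenstrat(tables: GenealogyTables, prefix) -> None:
    """Write EIGENSTRAT ``.geno``/``.snp``/``.ind`` files with the given prefix."""
    prefix = str(prefix)
    ids, node_pairs = _sampled_individuals(tables)
    names = [tables.indiv_names[i] for i in ids]
    order = np.argsort(tables.sites_position, kind="stable")
    geno = genotype_matrix(tables, node_pairs.reshape(-1))
    with open(prefix + ".geno", "w") as fh:
        for s in order:
            row = geno[s].reshape(-1, 2).sum(axis=1)
            fh.write("".join(str(int(v)) for v in row) + "\n")
    with open(prefix + ".snp", "w") as fh:
        for s in order:
            pos = int(tables.sites_position[s]) + 1
            fh.write(f"1_{pos}\t1\t0.0\t{pos}\tA\tT\n")
    with open(prefix + ".ind", "w") as fh:
        for i, name in zip(ids, names):
            pop = tables.population_names[tables.indiv_population[i]]
            fh.write(f"{name}\tU\t{pop}\n")
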