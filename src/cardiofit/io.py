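"""File formats: delimited-text traces, YAML manifests, JSON genomes,
HDF5 checkpoints.  Every writer has a reader that round-trips to an equal
in-memory object."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .ga import GAConfig, GAHistory, Organism
from .waveform import APTrace, BaselineSet

__all__ = [
    "save_trace", "load_trace", "save_baselines", "load_baselines",
    "save_genome", "load_genome", "save_history", "load_history",
    "save_checkpoint", "load_checkpoint", "file_sha256",
]


def save_trace(trace: APTrace, path):
    header = f"pcl_ms={trace.pcl:g} normalized={int(trace.normalized)}"
    np.savetxt(path, np.column_stack([trace.time, trace.v]),
               fmt="%.6f", delimiter="\t", header=header)


def load_trace(path, pcl: float | None = None) -> APTrace:
    normalized = False
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first[1:].split():
            if tok.startswith("pcl_ms=") and pcl is None:
                pcl = float(tok.split("=")[1])
            elif tok.startswith("normalized="):
                normalized = bool(int(tok.split("=")[1]))
    data = np.loadtxt(path, delimiter="\t")
    if pcl is None:
        raise ValueError("PCL not recorded in file and not given")
    return APTrace(time=data[:, 0], v=data[:, 1], pcl=pcl,
                   normalized=normalized)


def save_baselines(baselines: BaselineSet, directory):
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"mode": baselines.mode, "traces": {}}
    for pcl, trace in baselines.traces.items():
        fname = f"trace_{pcl:g}ms.txt"
        save_trace(trace, directory / fname)
        manifest["traces"][f"{pcl:g}"] = {
            "file": fname, "weight": float(baselines.weights[pcl])}
    with open(directory / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)


def load_baselines(directory) -> BaselineSet:
    directory = Path(directory)
    with open(directory / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    traces = {}
    weights = {}
    for key, entry in manifest["traces"].items():
        pcl = float(key)
        traces[pcl] = load_trace(directory / entry["file"], pcl=pcl)
        weights[pcl] = float(entry["weight"])
    return BaselineSet(traces=traces, weights=weights,
                       mode=manifest["mode"])


def save_genome(genome, names, path, fitness: float | None = None):
    data = {"genes": dict(zip(names, map(float, np.asarray(genome))))}
    if fitness is not None:
        data["fitness"] = float(fitness)
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


def load_genome(path, names=None):
    with open(path) as fh:
        data = json.load(fh)
    genes = data["genes"]
    if names is None:
        names = list(genes)
    return np.array([genes[n] for n in names]), data.get("fitness")


def save_history(history: GAHistory, path):
    arr = np.column_stack([
        np.arange(len(history.best_fitness)),
        history.best_fitness, history.mean_fitness])
    np.savetxt(path, arr, fmt=["%d", "%.8g", "%.8g"], delimiter="\t",
               header="generation\tbest_rmse\tmean_rmse")


def load_history(path) -> GAHistory:
    arr = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
    h = GAHistory()
    h.best_fitness = arr[:, 1].tolist()
    h.mean_fitness = arr[:, 2].tolist()
    h.generations_run = arr.shape[0]
    return h


def save_checkpoint(path, generation: int, population, history: GAHistory,
                    rng: np.random.Generator):
    """Snapshot a GA run: genomes, persisted states, fitness, history and
    the RNG state, sufficient to bit-reproduce the remaining generations."""
    with h5py.File(path, "w") as f:
        f.attrs["generation"] = generation
        f.attrs["rng_state"] = json.dumps(rng.bit_generator.state)
        f.create_dataset("genomes", data=np.array(
            [o.genome for o in population]))
        fit = np.array([np.nan if o.fitness is None else o.fitness
                        for o in population])
        f.create_dataset("fitness", data=fit)
        f.create_dataset("best_fitness", data=np.asarray(
            history.best_fitness))
        f.create_dataset("mean_fitness", data=np.asarray(
            history.mean_fitness))
        if history.best is not None:
            f.create_dataset("best_genome", data=history.best.genome)
            f.attrs["best_fit"] = history.best.fitness
        states = f.create_group("states")
        for i, org in enumerate(population):
            g = states.create_group(str(i))
            for pcl, st in org.states.items():
                if st is not None:
                    g.create_dataset(f"{pcl:g}", data=st)


def load_checkpoint(path):
    with h5py.File(path, "r") as f:
        generation = int(f.attrs["generation"])
        rng_state = json.loads(f.attrs["rng_state"])
        genomes = f["genomes"][...]
        fitness = f["fitness"][...]
        population = []
        for i in range(genomes.shape[0]):
            org = Organism(genomes[i].copy())
            org.fitness = None if np.isnan(fitness[i]) else float(fitness[i])
            g = f["states"][str(i)]
            org.states = {float(k): g[k][...] for k in g}
            population.append(org)
        history = GAHistory()
        history.best_fitness = f["best_fitness"][...].tolist()
        history.mean_fitness = f["mean_fitness"][...].tolist()
        history.generations_run = generation
        if "best_genome" in f:
            best = Organism(f["best_genome"][...])
            best.fitness = float(f.attrs["best_fit"])
            history.best = best
    return generation, population, history, rng_state


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
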