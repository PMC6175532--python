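"""Readers and writers for the package's on-disk formats.

All tabular artifacts are TSV with a header row; sequences are FASTA;
motifs are 4-column (A, C, G, T) matrices with an optional ``>name`` header
and ``#background`` line; scenarios and distributions are directories of
those plus a YAML manifest.  Bins are 1-based in every user-facing file.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ensemble_builder import Dimension, Ensemble, ParameterSpace
from .experiment_evaluation import (Abolished, BoundaryShift, PeakFraction,
                                    PerturbationExperiment, ProfileMatch,
                                    SiteMutagenesis, TFKnockout, Unchanged,
                                    VariantEnhancer)
from .model_distribution import (ClusteredEnsemble, EnsembleDistribution,
                                 ModelProbabilities, ScalingRecord, entropy)
from .synthetic_data import Scenario
from .thermo_model import Motif, ModelParameters, TFSpec, annotate_sites_for_tfs

__all__ = [
    "read_fasta", "write_fasta", "read_motif", "write_motif",
    "read_profiles", "write_profiles", "save_scenario", "load_scenario",
    "save_ensemble", "load_ensemble", "save_distribution",
    "load_distribution", "experiments_from_yaml", "space_to_dict",
    "space_from_dict",
]


# ------------------------------------------------------------------ sequences

def read_fasta(path) -> dict:
    """Named sequences from a FASTA file, uppercased; order preserved."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        invalid = set(seq) - set("ACGTN")
        if invalid:
            raise ValueError(
                f"{path}: record {rec.id!r} has invalid characters {sorted(invalid)}")
        records[rec.id] = seq
    return records


def write_fasta(path, sequences: dict) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# --------------------------------------------------------------------- motifs

def read_motif(path, pseudocount: float = 0.5, name: str | None = None) -> Motif:
    """A motif from a 4-column (A, C, G, T) count or frequency matrix.

    Rows that already sum to one (within 1e-6) are taken as frequencies and
    used as-is; otherwise they are treated as counts and smoothed with
    ``pseudocount``.  An optional ``>name`` header and ``#background a c g
    t`` line are honored.
    """
    path = Path(path)
    rows = []
    background = None
    file_name = name
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            file_name = line[1:].split()[0]
            continue
        if line.startswith("#"):
            fields = line[1:].split()
            if fields and fields[0].lower() == "background":
                background = np.array([float(x) for x in fields[1:]])
            continue
        fields = line.replace(",", " ").split()
        if len(fields) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
        try:
            rows.append([float(x) for x in fields])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric value") from exc
    if not rows:
        raise ValueError(f"{path}: no matrix rows found")
    matrix = np.array(rows)
    if np.any(matrix.sum(axis=1) <= 0):
        bad = int(np.flatnonzero(matrix.sum(axis=1) <= 0)[0]) + 1
        raise ValueError(f"{path}: matrix row {bad} sums to zero")
    motif_name = file_name or path.stem
    kwargs = {} if background is None else {"background": background}
    if np.allclose(matrix.sum(axis=1), 1.0, atol=1e-6):
        return Motif(name=motif_name, matrix=matrix, **kwargs)
    return Motif.from_counts(motif_name, matrix, pseudocount=pseudocount,
                             background=kwargs.get("background"))


def write_motif(path, motif: Motif) -> None:
    with open(path, "w") as fh:
        fh.write(f">{motif.name}\n")
        fh.write("#background " + " ".join(f"{x:.10g}" for x in motif.background) + "\n")
        for row in motif.matrix:
            fh.write(" ".join(f"{x:.10g}" for x in row) + "\n")


# ------------------------------------------------------------------- profiles

def read_profiles(path, n_bins: int) -> dict:
    """Named per-bin profiles from a TSV with a 1-based ``bin`` column.

    Every profile value must lie in [0, 1]; violations are reported with
    their row and column.
    """
    frame = pd.read_csv(path, sep="\t")
    if "bin" not in frame.columns:
        raise ValueError(f"{path}: missing 'bin' column")
    expected = np.arange(1, n_bins + 1)
    if len(frame) != n_bins or not np.array_equal(frame["bin"].to_numpy(), expected):
        raise ValueError(f"{path}: 'bin' column must be exactly 1..{n_bins}")
    profiles = {}
    for column in frame.columns:
        if column == "bin":
            continue
        values = frame[column].to_numpy(dtype=float)
        bad = np.flatnonzero((values < 0) | (values > 1) | ~np.isfinite(values))
        if len(bad):
            raise ValueError(
                f"{path}: value {values[bad[0]]!r} out of [0, 1] at bin "
                f"{bad[0] + 1}, column {column!r}")
        profiles[column] = values
    return profiles


def write_profiles(path, profiles: dict) -> None:
    lengths = {len(v) for v in profiles.values()}
    if len(lengths) != 1:
        raise ValueError("profiles have inconsistent lengths")
    n_bins = lengths.pop()
    frame = pd.DataFrame({"bin": np.arange(1, n_bins + 1)})
    for name, values in profiles.items():
        frame[name] = np.asarray(values, dtype=float)
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ------------------------------------------------------------------ scenarios

def save_scenario(directory, scenario: Scenario) -> None:
    """Write a scenario bundle: FASTA + motif files + profiles TSV + manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_fasta(directory / "enhancer.fasta", {"enhancer": scenario.sequence})
    for name, motif in scenario.motifs.items():
        write_motif(directory / f"motif_{name}.txt", motif)
    profiles = {tf.name: tf.concentration for tf in scenario.tfs}
    profiles["target"] = scenario.target
    for tf in scenario.tfs:
        if tf.attenuation_mask is not None:
            profiles[f"atten_mask_{tf.name}"] = tf.attenuation_mask
    write_profiles(directory / "profiles.tsv", profiles)
    manifest = {
        "name": scenario.name,
        "n_bins": int(scenario.n_bins),
        "seed": int(scenario.seed),
        "site_threshold": float(scenario.site_threshold),
        "coop_cutoff": float(scenario.coop_cutoff),
        "coop_pairs": [[a, b] for a, b in scenario.coop_pairs],
        "tfs": [{"name": tf.name, "role": tf.role, "protein": tf.protein,
                 "motif": tf.motif.name,
                 "attenuated": tf.attenuation_mask is not None}
                for tf in scenario.tfs],
        "ground_truth": (None if scenario.ground_truth is None
                         else _params_to_dict(scenario.ground_truth)),
    }
    (directory / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))


def load_scenario(directory) -> Scenario:
    directory = Path(directory)
    manifest = yaml.safe_load((directory / "manifest.yaml").read_text())
    sequence = read_fasta(directory / "enhancer.fasta")["enhancer"]
    n_bins = manifest["n_bins"]
    profiles = read_profiles(directory / "profiles.tsv", n_bins)
    motifs = {}
    tfs = []
    for entry in manifest["tfs"]:
        motif_name = entry["motif"]
        if motif_name not in motifs:
            motifs[motif_name] = read_motif(directory / f"motif_{motif_name}.txt")
        mask = profiles.get(f"atten_mask_{entry['name']}") if entry["attenuated"] else None
        tfs.append(TFSpec(name=entry["name"], role=entry["role"],
                          concentration=profiles[entry["name"]],
                          motif=motifs[motif_name], attenuation_mask=mask,
                          protein=entry.get("protein")))
    sites = annotate_sites_for_tfs(sequence, tfs, manifest["site_threshold"])
    ground_truth = (None if manifest["ground_truth"] is None
                    else _params_from_dict(manifest["ground_truth"]))
    return Scenario(
        name=manifest["name"], sequence=sequence, motifs=motifs, tfs=tfs,
        sites=sites, target=profiles["target"],
        coop_pairs=tuple(tuple(p) for p in manifest["coop_pairs"]),
        coop_cutoff=manifest["coop_cutoff"],
        site_threshold=manifest["site_threshold"],
        ground_truth=ground_truth, seed=manifest["seed"])


def _params_to_dict(params: ModelParameters) -> dict:
    return {
        "K": {k: float(v) for k, v in params.K.items()},
        "alpha": {k: float(v) for k, v in params.alpha.items()},
        "coop": {f"{a}|{b}": float(v) for (a, b), v in params.coop.items()},
        "q_btm": float(params.q_btm),
        "atten": {k: float(v) for k, v in params.atten.items()},
    }


def _params_from_dict(data: dict) -> ModelParameters:
    return ModelParameters(
        K=dict(data["K"]), alpha=dict(data["alpha"]),
        coop={tuple(k.split("|")): v for k, v in data.get("coop", {}).items()},
        q_btm=data["q_btm"], atten=dict(data.get("atten", {})))


# ------------------------------------------------------------------ ensembles

def space_to_dict(space: ParameterSpace) -> list:
    return [{"name": d.name, "lower": float(d.lower), "upper": float(d.upper),
             "scale": d.scale} for d in space.dims]


def space_from_dict(entries: list) -> ParameterSpace:
    return ParameterSpace([Dimension(**e) for e in entries])


def save_ensemble(path, ensemble: Ensemble) -> None:
    """One TSV row per model (parameters on natural scale + sse), with a
    YAML provenance sidecar ``<path>.meta.yaml``."""
    path = Path(path)
    frame = pd.DataFrame(ensemble.vectors, columns=ensemble.space.names)
    frame["sse"] = ensemble.scores
    frame.to_csv(path, sep="\t", index=False, float_format="%.12g")
    meta = {"space": space_to_dict(ensemble.space),
            "provenance": _plain(ensemble.provenance)}
    Path(str(path) + ".meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))


def load_ensemble(path) -> Ensemble:
    path = Path(path)
    meta = yaml.safe_load(Path(str(path) + ".meta.yaml").read_text())
    space = space_from_dict(meta["space"])
    frame = pd.read_csv(path, sep="\t")
    return Ensemble(vectors=frame[space.names].to_numpy(),
                    scores=frame["sse"].to_numpy(),
                    space=space, provenance=meta.get("provenance", {}))


def save_distribution(directory, dist: EnsembleDistribution) -> None:
    """Distribution bundle: the ensemble TSV plus cluster label and
    probability columns, long-format cluster covariances, and a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_ensemble(directory / "models.tsv", dist.ensemble)
    frame = pd.read_csv(directory / "models.tsv", sep="\t")
    frame["cluster"] = dist.clustered.labels + 1  # 1-based in files
    frame["p"] = dist.probabilities.p
    frame.to_csv(directory / "models.tsv", sep="\t", index=False,
                 float_format="%.12g")
    covs = dist.clustered.cluster_covs
    rows = [(c + 1, i + 1, j + 1, covs[c, i, j])
            for c in range(covs.shape[0])
            for i in range(covs.shape[1]) for j in range(covs.shape[2])]
    pd.DataFrame(rows, columns=["cluster", "row", "col", "value"]).to_csv(
        directory / "covariances.tsv", sep="\t", index=False, float_format="%.12g")
    manifest = {
        "entropy": float(dist.entropy),
        "n_clusters": int(dist.clustered.n_clusters),
        "selected": _plain(dist.clustered.selected),
        "scaling": {"mins": [float(x) for x in dist.scaling.mins],
                    "maxs": [float(x) for x in dist.scaling.maxs]},
    }
    (directory / "distribution.yaml").write_text(
        yaml.safe_dump(manifest, sort_keys=False))


def load_distribution(directory) -> EnsembleDistribution:
    directory = Path(directory)
    ensemble = load_ensemble(directory / "models.tsv")
    frame = pd.read_csv(directory / "models.tsv", sep="\t")
    manifest = yaml.safe_load((directory / "distribution.yaml").read_text())
    scaling = ScalingRecord(mins=np.array(manifest["scaling"]["mins"]),
                            maxs=np.array(manifest["scaling"]["maxs"]))
    labels = frame["cluster"].to_numpy(dtype=int) - 1
    p = frame["p"].to_numpy(dtype=float)
    cov_frame = pd.read_csv(directory / "covariances.tsv", sep="\t")
    n = manifest["n_clusters"]
    D = ensemble.vectors.shape[1]
    covs = np.zeros((n, D, D))
    covs[cov_frame["cluster"] - 1, cov_frame["row"] - 1, cov_frame["col"] - 1] = \
        cov_frame["value"]
    clustered = ClusteredEnsemble(
        scaled_models=scaling.transform(ensemble.vectors), labels=labels,
        cluster_covs=covs, selected=manifest.get("selected", {}))
    probs = ModelProbabilities(p=p, labels=labels)
    return EnsembleDistribution(ensemble=ensemble, scaling=scaling,
                                clustered=clustered, probabilities=probs,
                                entropy=entropy(probs))


# ---------------------------------------------------------------- experiments

_PERTURBATIONS = {
    "tf_knockout": lambda spec: TFKnockout(tf=spec["tf"]),
    "site_mutagenesis": lambda spec: SiteMutagenesis(
        tf=spec["tf"], strongest_k=spec.get("strongest_k", 1),
        positions=tuple(spec["positions"]) if "positions" in spec else None),
    "variant_enhancer": lambda spec: VariantEnhancer(sequence=spec["sequence"]),
}


def _criterion_from_spec(spec: dict, scenario: Scenario):
    kind = spec["kind"]
    if kind == "unchanged":
        return Unchanged(threshold=spec.get("threshold", 0.05))
    if kind == "profile_match":
        target = spec["target"]
        if isinstance(target, str):
            # "<profiles.tsv>:<column>" reference
            fname, _, column = target.rpartition(":")
            target = read_profiles(fname, scenario.n_bins)[column]
        target = np.asarray(target, dtype=float)
        if len(target) != scenario.n_bins:
            raise ValueError("profile_match target length mismatch")
        return ProfileMatch(target=target, threshold=spec.get("threshold", 0.05))
    if kind == "peak_fraction":
        return PeakFraction(lo=spec["lo"], hi=spec["hi"])
    if kind == "boundary_shift":
        return BoundaryShift(side=spec["side"], min_bins=spec.get("min_bins", 2.0))
    if kind == "abolished":
        return Abolished(max_level=spec.get("max_level", 0.1))
    raise ValueError(f"unknown criterion kind {kind!r}")


def experiments_from_yaml(path, scenario: Scenario) -> list[PerturbationExperiment]:
    """Parse experiment definitions (name, perturbation, criterion)."""
    entries = yaml.safe_load(Path(path).read_text())
    experiments = []
    for entry in entries:
        pert_spec = entry["perturbation"]
        kind = pert_spec["type"]
        if kind not in _PERTURBATIONS:
            raise ValueError(f"unknown perturbation type {kind!r}")
        experiments.append(PerturbationExperiment(
            name=entry["name"],
            perturbation=_PERTURBATIONS[kind](pert_spec),
            criterion=_criterion_from_spec(entry["criterion"], scenario)))
    return experiments


def _plain(obj):
    """Recursively convert numpy scalars for clean YAML output."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
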