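"""Batch orchestration: per-subject connectivity, group algebra, reports.

A study is a ``Study/Subject/Acquisition/Run`` tree (see ``mibca.io``).
``run_subject`` executes every stage whose inputs exist (missing
modalities are skipped with a logged notice); ``run_group`` assembles
subject stacks into mean/robustness/combined/hybrid matrices, graph
reports and group tests.  Stage failures are quarantined per subject so
a batch never aborts.  All thresholds default to the standard analysis
values: alpha 0.05 (Bonferroni corrected), robustness threshold 0.8,
Granger order 1, 10 null graphs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import algebra, anatomical, effective, functional, graph as graphm, io as mio
from . import groupstats, structural
from .types import ConnectivityMatrix, Parcellation, ROISignalSet, SubjectStack

logger = logging.getLogger("mibca")


@dataclass
class PipelineConfig:
    alpha: float = 0.05
    robustness_tau: float = 0.8
    s_bin_rule: str = "positive_count"
    granger_order: int = 1
    n_null_graphs: int = 10
    seed: int = 0
    pet_reference_roi: int | None = None
    group_variable: str = "age"
    group_threshold: float | None = 40.0
    stages: tuple[str, ...] = ("anatomical", "structural", "functional",
                               "effective", "pet")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        raw["stages"] = tuple(raw.get("stages", cls.stages))
        return cls(**raw)


def _load_parcellation(study_root: Path) -> Parcellation:
    return mio.read_label_volume(study_root / "parcellation.nii.gz")


def _load_roi_table_signals(path: Path, parc: Parcellation, modality: str,
                            sampling: float) -> ROISignalSet:
    df = mio.read_table(path)
    df = df.set_index("label_id").loc[parc.roi_ids]
    return ROISignalSet(values=df.to_numpy(dtype=float), roi_ids=parc.roi_ids,
                        sampling=sampling, modality=modality)


def _find_first(paths: list[Path], *names: str) -> Path | None:
    for run in paths:
        for name in names:
            hits = sorted(run.glob(name))
            if hits:
                return hits[0]
    return None


def run_subject(
    subject_id: str,
    acquisitions: dict[str, list[Path]],
    parc: Parcellation,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> dict[str, list[str]]:
    """Run every applicable per-subject stage; returns written artifacts.

    Returns a map stage -> list of written file names; stages without
    inputs are skipped (logged), and stage exceptions are caught and
    recorded under ``"failed"``.
    """
    config = config or PipelineConfig()
    out_dir = Path(out_dir) / subject_id
    written: dict[str, list[str]] = {}
    failed: list[str] = []

    def record(stage: str, names: list[str]) -> None:
        written[stage] = names
        logger.info("subject %s: stage %s -> %d files", subject_id, stage, len(names))

    # anatomical: morphometry table -> a-CMs
    morph_path = _find_first(acquisitions.get("smri", []), "morphometry.tsv")
    if "anatomical" in config.stages and morph_path is not None:
        try:
            morph = mio.read_table(morph_path)
            adir = out_dir / "smri"
            adir.mkdir(parents=True, exist_ok=True)
            names = []
            for measure in ("CT", "SA", "GMV", "volume"):
                if measure not in morph.columns:
                    continue
                if morph[measure].dropna().empty:
                    continue
                cm = anatomical.anatomical_cm(morph, measure, parc=parc)
                mio.write_matrix(cm, adir / f"a_cm_{measure.lower()}.txt")
                names.append(f"a_cm_{measure.lower()}.txt")
            mio.write_table(morph, adir / "morphometry.tsv")
            record("anatomical", names + ["morphometry.tsv"])
        except Exception:
            logger.exception("subject %s: anatomical stage failed", subject_id)
            failed.append("anatomical")

    # structural: streamlines -> s-CM trio + QC
    tract_path = _find_first(
        acquisitions.get("dti", []), "*.trk", "streamlines.txt", "*.txt"
    )
    if "structural" in config.stages and tract_path is not None:
        try:
            tract = mio.read_tractogram(tract_path, space_id=parc.space_id)
            assignments = structural.assign_streamlines(tract, parc)
            s_cm, len_cm, orient, qc = structural.structural_cm(
                assignments, parc.roi_ids
            )
            ddir = out_dir / "dti"
            ddir.mkdir(parents=True, exist_ok=True)
            mio.write_matrix(s_cm, ddir / "s_cm.txt")
            mio.write_matrix(len_cm, ddir / "length_cm.txt")
            for k, axis in enumerate("xyz"):
                mio.write_matrix(
                    ConnectivityMatrix(
                        values=orient[:, :, k], roi_ids=parc.roi_ids,
                        modality="s", weight_kind="orientation_vector",
                    ),
                    ddir / f"orientation_{axis}.txt",
                )
            s_bin = algebra.binarize(s_cm, rule=config.s_bin_rule)
            mio.write_matrix(s_bin, ddir / "s_bin.txt")
            with open(ddir / "qc.json", "w") as fh:
                json.dump(qc, fh)
            record("structural", ["s_cm.txt", "length_cm.txt", "s_bin.txt",
                                  "orientation_x.txt", "orientation_y.txt",
                                  "orientation_z.txt", "qc.json"])
        except Exception:
            logger.exception("subject %s: structural stage failed", subject_id)
            failed.append("structural")

    # functional + effective: BOLD ROI series
    bold_path = _find_first(acquisitions.get("fmri", []), "bold_roi.tsv")
    if "functional" in config.stages and bold_path is not None:
        try:
            bold = _load_roi_table_signals(bold_path, parc, "bold", 2.0)
            res = functional.pearson_fc(bold)
            f_bin, f_masked = functional.threshold_bonferroni(res, config.alpha)
            fdir = out_dir / "fmri"
            fdir.mkdir(parents=True, exist_ok=True)
            mio.write_matrix(res.r_matrix, fdir / "f_r.txt")
            mio.write_matrix(
                res.r_matrix.copy_with(res.p_matrix, weight_kind="probability"),
                fdir / "f_p.txt",
            )
            mio.write_matrix(f_bin, fdir / "f_bin.txt")
            mio.write_matrix(f_masked, fdir / "f_cm.txt")
            record("functional", ["f_r.txt", "f_p.txt", "f_bin.txt", "f_cm.txt"])
            if "effective" in config.stages:
                gc_res, e_bin, bidir = effective.effective_cm(
                    bold, order=config.granger_order, alpha=config.alpha
                )
                mio.write_matrix(gc_res.gc_matrix, fdir / "e_gc.txt")
                mio.write_matrix(e_bin, fdir / "e_bin.txt")
                mio.write_matrix(bidir, fdir / "e_bidirectional.txt")
                record("effective",
                       ["e_gc.txt", "e_bin.txt", "e_bidirectional.txt"])
        except Exception:
            logger.exception("subject %s: functional stage failed", subject_id)
            failed.append("functional")

    # PET: TACs -> PET-CM + SUV/rSUV
    tac_path = _find_first(acquisitions.get("pet", []), "tacs.tsv")
    if "pet" in config.stages and tac_path is not None:
        try:
            tacs = _load_roi_table_signals(tac_path, parc, "pet", 225.0)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = functional.pet_cm(tacs)
            pdir = out_dir / "pet"
            pdir.mkdir(parents=True, exist_ok=True)
            mio.write_matrix(res.r_matrix, pdir / "pet_r.txt")
            # frame-summed activity per ROI stands in for the summed-volume SUV
            suv = pd.DataFrame(
                {"label_id": parc.roi_ids, "SUV": tacs.values.sum(axis=1)}
            )
            ref = config.pet_reference_roi or parc.roi_ids[0]
            ref_val = float(suv.loc[suv["label_id"] == ref, "SUV"].iloc[0])
            suv["rSUV"] = suv["SUV"] / ref_val
            mio.write_table(suv, pdir / "suv.tsv")
            record("pet", ["pet_r.txt", "suv.tsv"])
        except Exception:
            logger.exception("subject %s: pet stage failed", subject_id)
            failed.append("pet")

    if failed:
        written["failed"] = failed
    if not written:
        logger.warning("subject %s: no applicable stages", subject_id)
    return written


def _collect_stack(
    out_root: Path, subjects: list[str], rel: str, modality: str,
    covariates: pd.DataFrame,
) -> SubjectStack | None:
    matrices = {}
    for sid in subjects:
        path = out_root / sid / rel
        if path.exists():
            matrices[sid] = mio.read_matrix(path)
    if not matrices:
        return None
    ids = sorted(matrices)
    return SubjectStack(subject_ids=ids, matrices=matrices,
                        covariates=covariates.loc[ids] if len(covariates) else covariates)


def run_group(
    study_root: str | Path,
    out_root: str | Path,
    config: PipelineConfig | None = None,
) -> dict:
    """Full group pass over an already-discovered study.

    Runs every subject, then for each modality builds mean-CM,
    robustness-CM and the combined matrix (mean masked at robustness >
    tau), the hybrid sf matrices, graph reports for the combined binary
    structural/functional graphs, and the between-group morphometry
    tests.  Returns a manifest dict (also written to ``manifest.json``).
    """
    config = config or PipelineConfig()
    study_root, out_root = Path(study_root), Path(out_root)
    index = mio.discover_study_tree(study_root)
    parc = _load_parcellation(study_root)
    out_root.mkdir(parents=True, exist_ok=True)

    processed = []
    for sid, acqs in index.subjects:
        result = run_subject(sid, acqs, parc, out_root, config)
        if result and set(result) != {"failed"}:
            processed.append(sid)
    if not processed:
        raise ValueError("zero successfully processed subjects")

    participants_path = study_root / "participants.tsv"
    covariates = (
        mio.read_table(participants_path).set_index("subject_id")
        if participants_path.exists()
        else pd.DataFrame()
    )

    gdir = out_root / "group"
    gdir.mkdir(exist_ok=True)
    manifest: dict = {"subjects": processed, "config": dataclasses.asdict(config)}

    stacks = {
        "s": _collect_stack(out_root, processed, "dti/s_cm.txt", "s", covariates),
        "f": _collect_stack(out_root, processed, "fmri/f_cm.txt", "f", covariates),
        "pet": _collect_stack(out_root, processed, "pet/pet_r.txt", "pet", covariates),
    }
    combined_bins: dict[str, ConnectivityMatrix] = {}
    for name, stack in stacks.items():
        if stack is None:
            continue
        mean = algebra.mean_cm(stack)
        if name == "s":
            bins = {s: algebra.binarize(stack.matrices[s]) for s in stack.subject_ids}
        else:
            bins = {
                s: stack.matrices[s].copy_with(
                    (stack.matrices[s].values != 0).astype(float),
                    weight_kind="binary",
                )
                for s in stack.subject_ids
            }
        bin_stack = SubjectStack(
            subject_ids=stack.subject_ids, matrices=bins, covariates=stack.covariates
        )
        robust = algebra.robustness_cm(bin_stack)
        comb = algebra.combined_cm(mean, robust, tau=config.robustness_tau)
        var = algebra.variance_cm(stack)
        for label, cm in (("mean", mean), ("robustness", robust),
                          ("combined", comb), ("variance", var)):
            mio.write_matrix(cm, gdir / f"{name}_{label}.txt")
        combined_bins[name] = comb.copy_with(
            (comb.values != 0).astype(float), weight_kind="binary"
        )

    # hybrid structural-functional set
    if stacks["s"] is not None and stacks["f"] is not None:
        shared = [s for s in stacks["s"].subject_ids
                  if s in stacks["f"].subject_ids]
        sf = {
            s: algebra.hybrid_sf(stacks["s"].matrices[s], stacks["f"].matrices[s])
            for s in shared
        }
        if sf:
            sf_stack = SubjectStack(subject_ids=shared, matrices=sf,
                                    covariates=covariates.loc[shared]
                                    if len(covariates) else covariates)
            mio.write_matrix(algebra.mean_cm(sf_stack), gdir / "sf_mean.txt")
        if "s" in combined_bins and "f" in combined_bins:
            direct, mediated = algebra.decompose_direct_mediated(
                combined_bins["s"], combined_bins["f"]
            )
            mio.write_matrix(direct, gdir / "sf_direct.txt")
            mio.write_matrix(mediated, gdir / "sf_mediated.txt")

    # graph reports on the combined binary graphs
    graph_summary = {}
    for name, b_cm in combined_bins.items():
        if b_cm.values.sum() == 0:
            continue
        try:
            rep = graphm.graph_report(
                b_cm, n_null=config.n_null_graphs, seed=config.seed
            )
        except ValueError:
            continue
        graph_summary[name] = {
            "mean_degree": rep.mean_degree,
            "mean_clustering": rep.mean_clustering,
            "char_path_length": rep.char_path_length,
            "small_worldness": rep.small_world.sigma,
            "modularity_Q": rep.modularity_Q,
        }
        pd.DataFrame(
            {"label_id": rep.roi_ids, "degree": rep.degree,
             "clustering": rep.clustering}
        ).to_csv(gdir / f"{name}_node_metrics.tsv", sep="\t", index=False)
    with open(gdir / "graph_metrics.json", "w") as fh:
        json.dump(graph_summary, fh, indent=1)
    manifest["graph_metrics"] = graph_summary

    # group tests on morphometry
    if len(covariates) and config.group_threshold is not None:
        try:
            g1, g2 = groupstats.split_groups(
                covariates.loc[processed], config.group_variable,
                threshold=config.group_threshold,
            )
            morph = {
                sid: mio.read_table(out_root / sid / "smri" / "morphometry.tsv")
                for sid in processed
                if (out_root / sid / "smri" / "morphometry.tsv").exists()
            }
            if morph and len(g1) >= 2 and len(g2) >= 2:
                tests = {}
                measures = [c for c in next(iter(morph.values())).columns
                            if c != "label_id"]
                for measure in measures:
                    frames = {}
                    for sid, tab in morph.items():
                        s = tab.set_index("label_id")[measure].dropna()
                        frames[sid] = s
                    df = pd.DataFrame(frames).T
                    df.columns = [f"roi{c}" for c in df.columns]
                    a = df.loc[[s for s in g1 if s in df.index]]
                    b = df.loc[[s for s in g2 if s in df.index]]
                    if len(a) < 2 or len(b) < 2 or df.isna().any().any():
                        continue
                    res = groupstats.groupwise_test(a, b, alpha=config.alpha)
                    res.table.insert(0, "measure", measure)
                    tests[measure] = res.table
                if tests:
                    all_tests = pd.concat(tests.values(), ignore_index=True)
                    mio.write_table(all_tests, gdir / "group_tests.tsv")
                    manifest["n_group_tests"] = int(len(all_tests))
        except ValueError as exc:
            logger.warning("group test skipped: %s", exc)

    with open(out_root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
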