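"""File formats, network configuration, and the end-to-end pipeline driver.

The pipeline reproduces the full analysis on a directory of per-subject ROI
tables: select each network's ROIs (reducing bilateral pairs where
configured), binarize per subject, concatenate per group, fit one pairwise
MEM per group per network, enumerate each group's energy landscape and its
local minima, tally the total comparison count M over all networks and both
groups, score every candidate minimum per subject under that subject's own
fitted MEM, and run Bonferroni-corrected two-sample t-tests.

ROI tables are TSV/CSV with a header row of ROI names and one row per time
point; the subject manifest is a two-column TSV (subject_id, group); the
network configuration is JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .binarize import BilateralMap, ROITimeSeries, binarize, concatenate_group, reduce_bilateral
from .compare import (
    CandidateState,
    ComparisonConfig,
    SignatureResult,
    bonferroni_threshold,
    extract_signatures,
    subject_state_energies,
)
from .core import BinaryPatternSeries, MEMParams, decode_state
from .fit import FitConfig, fit_mle
from .landscape import EnergyLandscape, build_disconnectivity_tree, build_landscape, minima_table

logger = logging.getLogger(__name__)

#: Per-network local-minimum counts published for the two-group aging study
#: (23 young / 47 old subjects) whose design this package's defaults emulate;
#: their sum is the comparison count M used for Bonferroni correction there.
AGING_STUDY_MINIMA_TALLY: Dict[str, int] = {
    "DMN": 11,
    "FPN": 21,
    "SMN": 7,
    "SAN": 52,
    "ATN": 24,
    "VIS": 4,
    "AUD": 6,
}

#: Hard cap on the post-reduction regions per network: the exhaustive MLE
#: becomes impractical beyond 12 regions.
MAX_NETWORK_REGIONS = 12


class ParseError(ValueError):
    """A data file is malformed; the message names the offending location."""


class ConfigError(ValueError):
    """The network configuration is inconsistent with itself or the data."""


# --------------------------------------------------------------------------
# ROI tables and manifests
# --------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_roi_table(path, subject_id: Optional[str] = None) -> ROITimeSeries:
    """Read a TSV/CSV ROI table (header = ROI names, rows = time points)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=_sep_for(path), header=0)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: file is empty") from exc
    if frame.shape[0] == 0:
        raise ParseError(f"{path}: header only, no time points")
    header_numeric = all(
        _is_number(str(c)) for c in frame.columns
    )
    if header_numeric:
        raise ParseError(f"{path}: first row looks numeric; ROI-name header missing")
    for col in frame.columns:
        series = pd.to_numeric(frame[col], errors="coerce")
        bad = series.isna() & frame[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ParseError(
                f"{path}: non-numeric value {frame[col].iloc[row]!r} at data "
                f"row {row + 1}, column {col!r}"
            )
        if series.isna().any():
            row = int(np.flatnonzero(series.isna())[0])
            raise ParseError(
                f"{path}: missing value at data row {row + 1}, column {col!r} "
                f"(ragged row?)"
            )
        frame[col] = series
    return ROITimeSeries(
        data=frame.to_numpy(dtype=float).T,
        roi_names=tuple(str(c) for c in frame.columns),
        subject_id=subject_id if subject_id is not None else path.stem,
    )


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_roi_table(series: ROITimeSeries, path) -> None:
    path = Path(path)
    frame = pd.DataFrame(series.data.T, columns=list(series.roi_names))
    frame.to_csv(path, sep=_sep_for(path), index=False)


def read_manifest(path) -> Dict[str, str]:
    """Two-column TSV (subject_id, group) -> ordered mapping."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", header=0, dtype=str)
    for col in ("subject_id", "group"):
        if col not in frame.columns:
            raise ParseError(f"{path}: manifest must have a {col!r} column")
    if frame["subject_id"].duplicated().any():
        dup = frame["subject_id"][frame["subject_id"].duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate subject_id {dup!r}")
    return dict(zip(frame["subject_id"], frame["group"]))


def write_manifest(groups: Dict[str, str], path) -> None:
    frame = pd.DataFrame(
        {"subject_id": list(groups), "group": [groups[s] for s in groups]}
    )
    frame.to_csv(Path(path), sep="\t", index=False)


# --------------------------------------------------------------------------
# network configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkSpec:
    """One resting-state network: ordered ROIs and optional bilateral reduction."""

    rois: Tuple[str, ...]
    bilateral_pairs: Tuple[Tuple[str, str, str], ...] = ()
    reduce: bool = False

    def __post_init__(self):
        rois = tuple(str(r) for r in self.rois)
        if len(set(rois)) != len(rois):
            raise ConfigError("ROI names must be unique within a network")
        pairs = tuple((str(l), str(r), str(m)) for l, r, m in self.bilateral_pairs)
        for l, r, _ in pairs:
            for name in (l, r):
                if name not in rois:
                    raise ConfigError(f"bilateral pair member {name!r} not a network ROI")
        object.__setattr__(self, "rois", rois)
        object.__setattr__(self, "bilateral_pairs", pairs)
        if self.reduce and 2 * len(pairs) != len(rois):
            raise ConfigError(
                "reduce=True requires a complete left/right pairing of the ROIs"
            )
        n_effective = len(rois) - len(pairs) if self.reduce else len(rois)
        if n_effective > MAX_NETWORK_REGIONS:
            raise ConfigError(
                f"network has {n_effective} effective regions; the exhaustive "
                f"MLE supports at most {MAX_NETWORK_REGIONS}"
            )

    @property
    def n_effective(self) -> int:
        return len(self.rois) - (len(self.bilateral_pairs) if self.reduce else 0)


@dataclass(frozen=True)
class NetworkConfig:
    networks: Dict[str, NetworkSpec]

    def to_json_dict(self) -> dict:
        return {
            "networks": {
                name: {
                    "rois": list(spec.rois),
                    "bilateral_pairs": [list(p) for p in spec.bilateral_pairs],
                    "reduce": spec.reduce,
                }
                for name, spec in self.networks.items()
            }
        }

    @classmethod
    def from_json_dict(cls, payload: dict) -> "NetworkConfig":
        if not isinstance(payload, dict) or "networks" not in payload:
            raise ConfigError("network config must be an object with a 'networks' key")
        networks = {}
        for name, body in payload["networks"].items():
            if "rois" not in body:
                raise ConfigError(f"network {name!r} lacks a 'rois' list")
            networks[str(name)] = NetworkSpec(
                rois=tuple(body["rois"]),
                bilateral_pairs=tuple(
                    tuple(p) for p in body.get("bilateral_pairs", ())
                ),
                reduce=bool(body.get("reduce", False)),
            )
        return cls(networks=networks)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path) -> "NetworkConfig":
        try:
            payload = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise ConfigError(f"{path}: invalid JSON ({exc})") from exc
        return cls.from_json_dict(payload)


def bilateral_pairs_from_names(rois: Sequence[str]) -> Tuple[Tuple[str, str, str], ...]:
    """Pair ROIs named ``<base>-L`` / ``<base>-R`` into (left, right, base)."""
    pairs = []
    names = set(rois)
    for name in rois:
        if name.endswith("-L") and name[:-2] + "-R" in names:
            pairs.append((name, name[:-2] + "-R", name[:-2]))
    return tuple(pairs)


def default_network_config() -> NetworkConfig:
    """The three AAL-defined networks with published node tables.

    FPN and SAN have 12 ROIs each and ATN 10, all within the exhaustive-MLE
    cap, so none needs bilateral reduction.
    """
    fpn = (
        "Superior frontal gyrus, dorsolateral-L",
        "Superior frontal gyrus, dorsolateral-R",
        "Superior frontal gyrus, orbital part-L",
        "Superior frontal gyrus, orbital part-R",
        "Middle frontal gyrus-L",
        "Middle frontal gyrus-R",
        "Middle frontal gyrus, orbital part-L",
        "Middle frontal gyrus, orbital part-R",
        "Inferior frontal gyrus, triangular part-L",
        "Inferior frontal gyrus, triangular part-R",
        "Inferior parietal, but supramarginal and angular gyri-L",
        "Inferior parietal, but supramarginal and angular gyri-R",
    )
    san = (
        "Middle frontal gyrus-L",
        "Middle frontal gyrus-R",
        "Inferior frontal gyrus, triangular part-L",
        "Inferior frontal gyrus, triangular part-R",
        "Insula-L",
        "Insula-R",
        "Anterior cingulate and paracingulate gyri-L",
        "Anterior cingulate and paracingulate gyri-R",
        "Median cingulate and paracingulate gyri-L",
        "Median cingulate and paracingulate gyri-R",
        "Superior parietal gyrus-L",
        "Superior parietal gyrus-R",
    )
    atn = (
        "Middle frontal gyrus-L",
        "Middle frontal gyrus-R",
        "Inferior frontal gyrus, triangular part-L",
        "Inferior frontal gyrus, triangular part-R",
        "Superior parietal gyrus-L",
        "Superior parietal gyrus-R",
        "Inferior parietal, but supramarginal and angular gyri-L",
        "Inferior parietal, but supramarginal and angular gyri-R",
        "Superior temporal gyrus-L",
        "Superior temporal gyrus-R",
    )
    return NetworkConfig(
        networks={
            "FPN": NetworkSpec(rois=fpn),
            "SAN": NetworkSpec(rois=san),
            "ATN": NetworkSpec(rois=atn),
        }
    )


def select_network(
    series: ROITimeSeries, config: NetworkConfig, name: str
) -> ROITimeSeries:
    """Subset and reorder a subject's ROI table to one network's node order.

    Applies the configured bilateral reduction (continuous-signal averaging)
    when the network's ``reduce`` flag is set.
    """
    if name not in config.networks:
        raise ConfigError(
            f"network {name!r} not configured (have {sorted(config.networks)})"
        )
    spec = config.networks[name]
    missing = [r for r in spec.rois if r not in series.roi_names]
    if missing:
        raise ConfigError(
            f"subject {series.subject_id!r} lacks configured ROIs: {missing}"
        )
    index = {r: i for i, r in enumerate(series.roi_names)}
    sub = ROITimeSeries(
        data=series.data[[index[r] for r in spec.rois]],
        roi_names=spec.rois,
        subject_id=series.subject_id,
    )
    if spec.reduce:
        sub = reduce_bilateral(sub, BilateralMap(pairs=spec.bilateral_pairs))
    return sub


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupLandscapeResult:
    group: str
    params: MEMParams
    landscape: EnergyLandscape
    converged: bool
    iterations: int
    final_mismatch: float


@dataclass(frozen=True)
class NetworkResult:
    network: str
    roi_names: Tuple[str, ...]
    groups: Dict[str, GroupLandscapeResult]
    candidates: Tuple[int, ...]
    signatures: List[SignatureResult]


@dataclass(frozen=True)
class PipelineReport:
    networks: Dict[str, NetworkResult]
    minima_tally: Dict[str, int]
    m_comparisons: int
    alpha: float
    corrected_alpha: float
    test_flavor: str
    provenance: Dict[str, str]

    def to_json_dict(self) -> dict:
        payload = {
            "alpha": self.alpha,
            "m_comparisons": self.m_comparisons,
            "corrected_alpha": self.corrected_alpha,
            "test_flavor": self.test_flavor,
            "minima_tally": dict(sorted(self.minima_tally.items())),
            "provenance": dict(sorted(self.provenance.items())),
            "networks": {},
        }
        for name, net in sorted(self.networks.items()):
            payload["networks"][name] = {
                "roi_names": list(net.roi_names),
                "candidates": list(net.candidates),
                "groups": {
                    g: {
                        "h": [round(x, 12) for x in res.params.h],
                        "J": [[round(x, 12) for x in row] for row in res.params.J],
                        "converged": res.converged,
                        "iterations": res.iterations,
                        "final_mismatch": res.final_mismatch,
                        "local_minima": [
                            {
                                "state": s,
                                "energy": round(float(res.landscape.energies[s - 1]), 12),
                            }
                            for s in res.landscape.local_minima
                        ],
                    }
                    for g, res in sorted(net.groups.items())
                },
                "signatures": [
                    {
                        "state": sig.state,
                        "pattern": sig.pattern,
                        "t": round(sig.t_statistic, 12),
                        "p": float(f"{sig.p_value:.12g}"),
                        "group_means": {
                            g: round(m, 12) for g, m in sorted(sig.group_means.items())
                        },
                        "significant": sig.significant,
                    }
                    for sig in net.signatures
                ],
            }
        return payload

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict(), indent=2, sort_keys=True)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())


def signatures_table(report: PipelineReport) -> pd.DataFrame:
    """All tested states as one table, sorted by p within network."""
    rows = []
    for name, net in sorted(report.networks.items()):
        for sig in net.signatures:
            row = {
                "network": name,
                "state": sig.state,
                "pattern": sig.pattern,
                "t": sig.t_statistic,
                "p": sig.p_value,
                "corrected_alpha": sig.corrected_alpha,
                "significant": sig.significant,
            }
            for g, m in sorted(sig.group_means.items()):
                row[f"mean_energy_{g}"] = m
            rows.append(row)
    return pd.DataFrame(rows)


def _config_hash(*payloads) -> str:
    blob = json.dumps(payloads, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(
    subjects: Dict[str, ROITimeSeries],
    groups: Dict[str, str],
    network_config: NetworkConfig,
    fit_config: Optional[FitConfig] = None,
    alpha: float = 0.05,
    test_flavor: str = "pooled",
    networks: Optional[Sequence[str]] = None,
) -> PipelineReport:
    """Run the whole analysis and return a deterministic report.

    Steps per network: select/reduce ROIs -> binarize per subject ->
    concatenate per group -> fit one MEM per group -> enumerate the
    landscape and its local minima -> pool the minima tally into M ->
    fit each subject's own MEM and score every candidate state ->
    two-sample t-tests at the Bonferroni level alpha / M.
    """
    fit_config = fit_config or FitConfig()
    names = list(networks) if networks is not None else sorted(network_config.networks)
    subject_ids = sorted(subjects)
    missing = [s for s in subject_ids if s not in groups]
    if missing:
        raise ConfigError(f"subjects missing from manifest: {missing}")
    labels = sorted(set(groups[s] for s in subject_ids))
    if len(labels) != 2:
        raise ConfigError(f"need exactly two groups, got {labels}")
    for lab in labels:
        if sum(1 for s in subject_ids if groups[s] == lab) < 2:
            raise ConfigError(f"group {lab!r} has fewer than 2 subjects")

    # stage 1: per-network per-group landscapes
    per_network: Dict[str, dict] = {}
    tally: Dict[str, int] = {}
    for name in names:
        logger.info("network %s: binarizing %d subjects", name, len(subject_ids))
        binarized: Dict[str, BinaryPatternSeries] = {}
        for sid in subject_ids:
            try:
                binarized[sid] = binarize(select_network(subjects[sid], network_config, name))
            except ValueError as exc:
                raise type(exc)(f"network {name!r}, subject {sid!r}: {exc}") from exc
        roi_names = binarized[subject_ids[0]].roi_names
        group_results: Dict[str, GroupLandscapeResult] = {}
        for lab in labels:
            concat = concatenate_group(
                [binarized[s] for s in subject_ids if groups[s] == lab]
            )
            logger.info(
                "network %s, group %s: fitting MEM to %d concatenated volumes",
                name, lab, concat.t_max,
            )
            fit = fit_mle(concat, fit_config)
            scape = build_landscape(fit.params)
            group_results[lab] = GroupLandscapeResult(
                group=lab,
                params=fit.params,
                landscape=scape,
                converged=fit.converged,
                iterations=fit.iterations,
                final_mismatch=fit.final_mismatch,
            )
        tally[name] = sum(
            len(res.landscape.local_minima) for res in group_results.values()
        )
        per_network[name] = {
            "roi_names": roi_names,
            "binarized": binarized,
            "groups": group_results,
        }

    m_comparisons = sum(tally.values())
    corrected = bonferroni_threshold(alpha, m_comparisons)

    # stage 2: per-subject energies at candidate states, then t-tests
    networks_out: Dict[str, NetworkResult] = {}
    for name in names:
        info = per_network[name]
        group_results = info["groups"]
        candidates = sorted(
            {s for res in group_results.values() for s in res.landscape.local_minima}
        )
        n_regions = len(info["roi_names"])
        energies_by_subject: Dict[str, np.ndarray] = {}
        for sid in subject_ids:
            try:
                energies_by_subject[sid] = subject_state_energies(
                    info["binarized"][sid], candidates, fit_config
                )
            except ArithmeticError as exc:
                raise type(exc)(
                    f"network {name!r}, subject {sid!r}: {exc}"
                ) from exc
        cand_objects = []
        for j, state in enumerate(candidates):
            samples = {
                lab: np.array(
                    [
                        energies_by_subject[s][j]
                        for s in subject_ids
                        if groups[s] == lab
                    ]
                )
                for lab in labels
            }
            cand_objects.append(
                CandidateState(
                    network=name,
                    state=state,
                    n_regions=n_regions,
                    group_energies=samples,
                )
            )
        signatures = extract_signatures(
            cand_objects,
            ComparisonConfig(
                alpha=alpha, test_flavor=test_flavor, m_comparisons=m_comparisons
            ),
        )
        networks_out[name] = NetworkResult(
            network=name,
            roi_names=info["roi_names"],
            groups=group_results,
            candidates=tuple(candidates),
            signatures=signatures,
        )

    provenance = {
        "config_hash": _config_hash(
            network_config.to_json_dict(),
            {
                "alpha": alpha,
                "test_flavor": test_flavor,
                "learning_rate": fit_config.learning_rate,
                "tolerance": fit_config.tolerance,
                "max_iterations": fit_config.max_iterations,
            },
        ),
        "n_subjects": str(len(subject_ids)),
        "groups": ",".join(f"{lab}:{sum(1 for s in subject_ids if groups[s] == lab)}" for lab in labels),
    }
    return PipelineReport(
        networks=networks_out,
        minima_tally=tally,
        m_comparisons=m_comparisons,
        alpha=alpha,
        corrected_alpha=corrected,
        test_flavor=test_flavor,
        provenance=provenance,
    )


def load_dataset(data_dir, manifest_path=None) -> Tuple[Dict[str, ROITimeSeries], Dict[str, str]]:
    """Load every manifest subject's ROI table from a dataset directory.

    Tables are ``<subject_id>.tsv`` (or ``.csv``) inside ``data_dir``; the
    manifest defaults to ``manifest.tsv`` in the same directory.
    """
    data_dir = Path(data_dir)
    manifest_path = Path(manifest_path) if manifest_path else data_dir / "manifest.tsv"
    groups = read_manifest(manifest_path)
    subjects = {}
    for sid in groups:
        for suffix in (".tsv", ".csv"):
            candidate = data_dir / f"{sid}{suffix}"
            if candidate.exists():
                subjects[sid] = read_roi_table(candidate, subject_id=sid)
                break
        else:
            raise ParseError(f"no ROI table found for subject {sid!r} in {data_dir}")
    return subjects, groups
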