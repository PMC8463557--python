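"""End-to-end orchestration from raw spectra to the full result bundle.

Fixed stage order: read -> trim -> sqrt -> smooth -> SNIP removal -> TIC ->
peak detection -> binning -> frequency filter -> Hellinger -> statistics
(Ward + AU/BP, feature ranking, NMDS, dispersion homogeneity, PERMANOVA,
peak-pattern table). Stage failures abort with the stage name and the
offending input id; per-stage counts are logged.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import features as feat
from . import preprocess as pp
from .cluster import Dendrogram, au_bp, to_newick
from .config import PipelineConfig
from .distance import DistanceMatrix, bray_curtis, euclidean_distances
from .features import FeatureMatrix
from .ordination import OrdinationResult, nmds
from .permtests import PermTestResult, dispersion_homogeneity, permanova
from .ranking import FeatureRanking, dda_rank
from .spectrum import RawSpectrum, read_spectrum

logger = logging.getLogger("maldiclust")

__all__ = ["PipelineError", "PipelineResult", "run_pipeline", "load_spectra"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and offending input id."""

    def __init__(self, stage: str, message: str, input_id: str | None = None):
        self.stage = stage
        self.input_id = input_id
        where = f" [input: {input_id}]" if input_id else ""
        super().__init__(f"stage '{stage}' failed{where}: {message}")


@dataclass
class PipelineResult:
    feature_matrix: FeatureMatrix
    hellinger_matrix: FeatureMatrix
    dendrogram: Dendrogram | None = None
    ranking: FeatureRanking | None = None
    ordination: OrdinationResult | None = None
    permanova: PermTestResult | None = None
    dispersion: PermTestResult | None = None
    patterns: pd.DataFrame | None = None
    stats_error: str | None = None
    counts: dict = field(default_factory=dict)


def load_spectra(input_dir: str | Path) -> list[RawSpectrum]:
    """Load spectra from a directory, via its manifest when present."""
    input_dir = Path(input_dir)
    manifest = input_dir / "manifest.csv"
    spectra: list[RawSpectrum] = []
    if manifest.exists():
        with open(manifest) as fh:
            for row in csv.DictReader(fh):
                s = read_spectrum(input_dir / row["filename"])
                if row.get("species_label"):
                    s.meta["label"] = row["species_label"]
                s.meta.setdefault("spectrum_id", Path(row["filename"]).stem)
                spectra.append(s)
    else:
        for path in sorted(input_dir.glob("*.txt")):
            s = read_spectrum(path)
            s.meta.setdefault("spectrum_id", path.stem)
            spectra.append(s)
    if not spectra:
        raise PipelineError("read", f"no spectra found in {input_dir}")
    return spectra


def run_pipeline(
    config: PipelineConfig,
    spectra: Sequence[RawSpectrum] | None = None,
) -> PipelineResult:
    """Run the full analysis; writes outputs when ``config.output_dir`` is set.

    Preprocessing outputs (feature matrices) are produced even when the
    statistical stages are impossible (e.g. a single species label); in
    that case the result carries ``stats_error`` and, if an output
    directory is configured, the matrices are still written before the
    error is raised.
    """
    if spectra is None:
        if config.input_dir is None:
            raise PipelineError("read", "no spectra given and no input_dir configured")
        spectra = load_spectra(config.input_dir)
    params = config.processing_params()
    counts: dict = {"spectra_read": len(spectra)}
    logger.info("read %d spectra", len(spectra))

    # stage seeds derived from the pipeline seed so stages rerun in isolation
    ss = np.random.SeedSequence(config.seed)
    seed_boot, seed_nmds, seed_perm = (int(c.generate_state(1)[0]) for c in ss.spawn(3))

    processed: list[RawSpectrum] = []
    peaklists = []
    for s in spectra:
        sid = str(s.meta.get("spectrum_id", "?"))
        try:
            q = pp.preprocess(s, params)
            processed.append(q)
            peaklists.append(
                pp.detect_peaks(q, params.snr_threshold, params.peak_half_window)
            )
        except ValueError as exc:
            raise PipelineError("preprocess", str(exc), sid) from exc
    counts["peaks_detected"] = int(sum(len(pl) for pl in peaklists))
    logger.info("detected %d peaks in total", counts["peaks_detected"])

    try:
        binning = feat.bin_peaks(peaklists, params.bin_tolerance_rel)
        counts["bins"] = int(binning.bin_masses.size)
        matrix = feat.build_feature_matrix(binning, params.min_frequency)
        counts["columns_kept"] = matrix.shape[1]
        counts["columns_dropped"] = counts["bins"] - matrix.shape[1]
        hell = feat.hellinger(matrix)
    except ValueError as exc:
        raise PipelineError("features", str(exc)) from exc
    logger.info(
        "feature matrix: %d x %d (%d columns dropped)",
        matrix.shape[0], matrix.shape[1], counts["columns_dropped"],
    )

    provenance = [f"config={config.digest()}", f"seed={config.seed}"]
    matrix.comments = provenance + [f"counts={json.dumps(counts, sort_keys=True)}"]
    hell.comments = list(matrix.comments)

    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        matrix.to_csv(outdir / "feature_matrix.csv")
        hell.to_csv(outdir / "feature_matrix_hellinger.csv")

    result = PipelineResult(matrix, hell, counts=counts)
    n_labels = len(set(hell.labels))
    if n_labels < 2 or len(hell.ids) < 2:
        result.stats_error = (
            f"statistics need >= 2 spectra from >= 2 labels, got "
            f"{len(hell.ids)} spectra / {n_labels} label(s)"
        )
        raise PipelineError("statistics", result.stats_error)

    try:
        euc = euclidean_distances(hell)
        dendro = au_bp(hell, config.bootstrap_params(seed_boot))
        result.dendrogram = dendro
        ranking_input = hell if config.dda_on_hellinger else matrix
        result.ranking = dda_rank(ranking_input)
        dist: DistanceMatrix = (
            bray_curtis(hell) if config.nmds_distance == "braycurtis" else euc
        )
        result.ordination = nmds(
            dist, k=config.nmds_k, n_restarts=config.nmds_restarts, seed=seed_nmds
        )
        result.dispersion = dispersion_homogeneity(dist)
        result.permanova = permanova(dist, n_perm=config.n_permutations, seed=seed_perm)
        result.patterns = feat.peak_patterns(hell, params.pattern_min_frequency)
    except ValueError as exc:
        raise PipelineError("statistics", str(exc)) from exc

    if outdir is not None:
        _write_stats(result, outdir, provenance)
    return result


def _write_stats(result: PipelineResult, outdir: Path, provenance: list[str]) -> None:
    assert result.dendrogram is not None
    (outdir / "dendrogram.nwk").write_text(to_newick(result.dendrogram) + "\n")
    assert result.ranking is not None
    result.ranking.to_csv(outdir / "ranking.csv")
    ord_res = result.ordination
    assert ord_res is not None
    with open(outdir / "nmds.csv", "w") as fh:
        for line in provenance:
            fh.write(f"# {line}\n")
        fh.write(f"# stress={ord_res.stress!r}\n")
        k = ord_res.coordinates.shape[1]
        fh.write("id,label," + ",".join(f"axis{i + 1}" for i in range(k)) + "\n")
        for i, (sid, lab) in enumerate(zip(ord_res.ids, ord_res.labels)):
            coords = ",".join(repr(float(v)) for v in ord_res.coordinates[i])
            fh.write(f"{sid},{lab},{coords}\n")
    assert result.permanova is not None and result.dispersion is not None
    summary = {
        "permanova": {
            "pseudo_F": result.permanova.statistic,
            "p_value": result.permanova.p_value,
            "n_permutations": result.permanova.n_permutations,
        },
        "dispersion_homogeneity": {
            "F": result.dispersion.statistic,
            "p_value": result.dispersion.p_value,
            "method": result.dispersion.method,
        },
        "nmds_stress": ord_res.stress,
        "counts": result.counts,
        "provenance": provenance,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    assert result.patterns is not None
    result.patterns.to_csv(outdir / "peak_patterns.csv")
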