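"""End-to-end orchestration: SAM/reads in, abundance table out."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from . import alignment as aln
from . import gibbs
from .reference import ReferenceSet, load_reference


class PipelineError(RuntimeError):
    """Failure of a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """Everything a full estimation run needs.

    When ``sam_path`` is None the built-in matcher aligns the reads
    against the reference at ``max_error_rate`` instead of reading an
    external mapper's SAM.
    """

    reference_path: str | Path
    reads_path: str | Path
    output_path: str | Path
    sam_path: str | Path | None = None
    taxonomy_path: str | Path | None = None
    max_error_rate: float = 0.10
    alpha: float | list[float] = 1.0
    burn_in_sweeps: int = 1000
    kept_samples: int = 1000
    thinning: int = 1
    seed: int = 0
    convergence_tolerance: float | None = None
    drop_undetected: bool = False


@dataclass
class PipelineResult:
    summary: gibbs.PosteriorSummary
    taxon_abundance: dict[str, float] | None
    output_path: Path


def load_taxonomy(path: str | Path) -> dict[str, str]:
    """Two-column TSV (reference_id, taxon) -> mapping."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            ref_id, _, taxon = line.partition("\t")
            if not taxon:
                raise ValueError(f"taxonomy line without two columns: {line!r}")
            out[ref_id] = taxon
    return out


def write_abundance_tsv(
    summary: gibbs.PosteriorSummary,
    path: str | Path,
    config: PipelineConfig | None = None,
) -> None:
    """Write the abundance report with a run-metadata header.

    Numeric formatting is fixed so that identical runs produce
    byte-identical files.
    """
    lines = ["# coremix abundance estimate"]
    alpha_str = ",".join(f"{a:.10g}" for a in summary.alpha)
    meta = (
        f"# seed={summary.seed} alpha={alpha_str} "
        f"kept_samples={summary.kept_samples}"
    )
    if config is not None:
        meta += (
            f" burn_in={config.burn_in_sweeps} thinning={config.thinning}"
            f" max_error_rate={config.max_error_rate:.10g}"
        )
    lines.append(meta)
    lines.append(
        f"# reads_total={summary.n_reads_total} "
        f"assigned={summary.n_assigned} "
        f"unassigned_fraction={summary.unassigned_fraction:.6f}"
    )
    lines.append("reference_id\tmean_count\ttheta_hat\tabundance_hat")
    for i, rid in enumerate(summary.ref_ids):
        lines.append(
            f"{rid}\t{summary.mean_counts[i]:.10g}\t"
            f"{summary.theta_hat[i]:.10g}\t{summary.abundance_hat[i]:.10g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """parse → filter → read table → Φ → Gibbs → abundances (→ roll-up).

    Writes the abundance TSV to ``config.output_path``; a fixed seed makes
    the output byte-identical across runs. Any stage error is re-raised as
    :class:`PipelineError` naming the stage.
    """
    for label, p in (
        ("reference", config.reference_path),
        ("reads", config.reads_path),
        ("sam", config.sam_path),
        ("taxonomy", config.taxonomy_path),
    ):
        if p is not None and not Path(p).exists():
            raise PipelineError(label, f"input file not found: {p}")

    try:
        refset = load_reference(config.reference_path)
    except ValueError as exc:
        raise PipelineError("reference", str(exc)) from exc

    try:
        read_table = aln.build_read_table(config.reads_path)
    except ValueError as exc:
        raise PipelineError("reads", str(exc)) from exc

    try:
        if config.sam_path is not None:
            hits = aln.parse_sam(config.sam_path, refset)
        else:
            from .simulate import simulate_alignment

            hits = simulate_alignment(
                read_table, refset, config.max_error_rate
            )
        hits = aln.filter_high_quality(hits, config.max_error_rate)
    except ValueError as exc:
        raise PipelineError("alignment", str(exc)) from exc

    try:
        phi = aln.estimate_phi(read_table, hits, refset)
    except (KeyError, ValueError) as exc:
        raise PipelineError("phi", str(exc)) from exc

    try:
        cfg = gibbs.GibbsConfig(
            burn_in_sweeps=config.burn_in_sweeps,
            kept_samples=config.kept_samples,
            thinning=config.thinning,
            seed=config.seed,
            convergence_tolerance=config.convergence_tolerance,
        )
        summary = gibbs.run_gibbs(
            read_table, phi, config.alpha, cfg, refset.lengths
        )
        if config.drop_undetected:
            summary = summary.detected_only()
    except ValueError as exc:
        raise PipelineError("gibbs", str(exc)) from exc

    taxon_abundance = None
    if config.taxonomy_path is not None:
        try:
            taxonomy = load_taxonomy(config.taxonomy_path)
            taxon_abundance = gibbs.aggregate_abundance(
                dict(zip(summary.ref_ids, summary.abundance_hat)), taxonomy
            )
        except (KeyError, ValueError) as exc:
            raise PipelineError("taxonomy", str(exc)) from exc

    write_abundance_tsv(summary, config.output_path, config)
    if taxon_abundance is not None:
        taxon_path = Path(config.output_path).with_suffix(".taxa.tsv")
        with open(taxon_path, "w") as fh:
            fh.write("taxon\tabundance\n")
            for taxon, value in taxon_abundance.items():
                fh.write(f"{taxon}\t{value:.10g}\n")
    return PipelineResult(summary, taxon_abundance, Path(config.output_path))


def read_config_file(path: str | Path) -> dict[str, str]:
    """Flat ``key = value`` configuration mirroring the CLI flags."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(
                    f"{path}:{lineno}: expected 'key = value', got {line!r}"
                )
            key, _, value = line.partition("=")
            out[key.strip().replace("-", "_")] = value.strip()
    return out
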