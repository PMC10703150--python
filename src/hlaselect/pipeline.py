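"""End-to-end orchestration: config, run directory, manifest.

A run takes an alignment plus frequency table (real or synthetic), fits the
per-population regressions, evaluates held-out accuracy, computes Sβ with
its scrambled-frequency null, the region comparisons and the amino-acid
enrichment, and optionally the codon chi-square and depth stages.  Every
output table is written under one run directory together with a manifest
recording the configuration hash and seed, so a run is reproducible
byte-for-byte from its manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .io import (
    AlignedAlleleSet,
    FrequencyTable,
    RegionDefinition,
    load_regions,
    read_alignment,
    read_frequency_table,
)
from .regression import encode, evaluate, extract_beta, fit, split
from .selection import (
    PipelineConfig,
    aa_enrichment,
    null_model,
    region_compare,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated settings for one pipeline run."""

    alignment: str
    frequencies: str
    out_dir: str
    regions: str | None = None
    mode: str = "all-loci"
    kind: str = "linear-svr"
    hyperparameters: dict = field(default_factory=dict)
    min_minority: int = 3
    null_replicates: int = 100
    train_fraction: float = 0.8
    seed: int = 0
    run_dnds: bool = False
    nt_alignment: str | None = None

    def validate(self) -> None:
        for label, path in (("alignment", self.alignment),
                            ("frequencies", self.frequencies)):
            if not Path(path).exists():
                raise FileNotFoundError(f"{label} path {path!r} does not exist")
        if self.regions is not None and not Path(self.regions).exists():
            raise FileNotFoundError(f"regions path {self.regions!r} does not exist")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)


def run_pipeline(
    config: RunConfig,
    alleles: AlignedAlleleSet | None = None,
    table: FrequencyTable | None = None,
    regions: RegionDefinition | None = None,
) -> Path:
    """Execute all stages and write results under the run directory.

    In-memory objects may be passed to bypass file reads (the synthetic
    path); otherwise inputs are loaded from the configured paths.  Any
    stage error aborts the run with the stage named, leaving the outputs of
    completed stages in place.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": asdict(config),
        "config_hash": config.digest(),
        "version": __version__,
        "stages": {},
    }

    def stage(name):
        logger.info("stage %s", name)
        manifest["stages"][name] = {"started": time.time()}
        return time.time()

    def done(name, t0, **info):
        manifest["stages"][name].update(seconds=round(time.time() - t0, 3),
                                        **info)

    try:
        t0 = stage("load")
        if alleles is None:
            alleles = read_alignment(config.alignment)
        if table is None:
            table = read_frequency_table(config.frequencies)
        if regions is None:
            regions = load_regions(config.regions)
        if regions.excluded_alleles:
            keep = [n for n in table.alleles()
                    if n not in set(regions.excluded_alleles)]
            table = FrequencyTable(
                {k: v for k, v in table.entries.items() if k[1] in set(keep)},
                populations=list(table.populations),
            )
        done("load", t0, n_alleles=len(table.alleles()),
             n_populations=len(table.populations))

        # per-population fit with held-out evaluation
        t0 = stage("fit")
        pconf = PipelineConfig(mode=config.mode, kind=config.kind,
                               hyperparameters=config.hyperparameters or None,
                               min_minority=config.min_minority)
        rho_rows = []
        for pop in table.populations:
            dataset = encode(alleles, table.restrict(pop), mode=config.mode,
                             min_minority=config.min_minority)
            train, test = split(dataset, config.train_fraction,
                                seed=config.seed)
            f = fit(train, kind=config.kind,
                    hyperparameters=config.hyperparameters or None,
                    seed=config.seed, population=pop)
            rho, p = evaluate(f, test)
            rho_rows.append({"population": pop, "rho": rho, "p": p,
                             "n_train": len(train.rows),
                             "n_test": len(test.rows)})
        pd.DataFrame(rho_rows).to_csv(out / "rho.tsv", sep="\t", index=False)
        done("fit", t0, populations=len(rho_rows))

        # selection score with permutation null (full-data fits)
        t0 = stage("sbeta")
        scores = null_model(alleles, table, pconf,
                            n_replicates=config.null_replicates,
                            seed=config.seed)
        frame = scores.to_frame()
        frame.to_csv(out / "sbeta.tsv", sep="\t", index=False)
        done("sbeta", t0, n_positions=len(scores.positions),
             n_significant=int(frame["significant"].sum()))

        # beta matrix from the full-data fits
        t0 = stage("beta")
        from .selection import fit_all_populations

        beta = fit_all_populations(alleles, table, pconf, seed=config.seed)
        beta_rows = [
            {"population": pop, "position": pos, "amino_acid": aa, "beta": b}
            for (pop, pos, aa), b in sorted(beta.values.items())
        ]
        pd.DataFrame(beta_rows).to_csv(out / "beta.tsv", sep="\t", index=False)
        done("beta", t0, n_coefficients=len(beta_rows))

        # region comparisons
        t0 = stage("regions")
        reports = {}
        for scheme in ("four-region", "exon", "pb-vs-npb"):
            try:
                reports[scheme] = region_compare(scores, regions,
                                                 scheme).to_dict()
            except ValueError as exc:
                reports[scheme] = {"error": str(exc)}
        (out / "regions.json").write_text(json.dumps(reports, indent=2))
        done("regions", t0)

        # amino-acid enrichment over significant non-PB positions
        t0 = stage("enrichment")
        pb = regions.peptide_binding
        sig_npb = {p for p in scores.positions
                   if scores.significant.get(p) and p not in pb}
        if sig_npb:
            enrich = aa_enrichment(beta, sig_npb, seed=config.seed)
            enrich.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            done("enrichment", t0, n_positions=len(sig_npb))
        else:
            done("enrichment", t0, skipped="no significant non-PB positions")

        if config.run_dnds and config.nt_alignment:
            t0 = stage("dnds")
            from .dnds import codon_chi_square
            from .io import read_codon_alignment

            nt = read_codon_alignment(config.nt_alignment).drop_ambiguous()
            codon_chi_square(nt).to_csv(out / "dnds.tsv", sep="\t",
                                        index=False)
            done("dnds", t0, n_codons=nt.n_codons)
    except Exception as exc:
        failed = [n for n, s in manifest["stages"].items()
                  if "seconds" not in s]
        manifest["error"] = {"stage": failed[-1] if failed else "unknown",
                             "message": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
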