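"""End-to-end workflows: alignment -> statistics -> model -> design / fold.

A :class:`RunConfig` collects every tunable of the pipeline in one
serialisable object; :func:`run_workflow` executes the requested workflow,
writes versioned outputs plus the resolved config next to them, and returns
a manifest with a checksum per artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import metropolis_design, mutation_scan
from .folding import ContactRestraints, TorsionConstraint, iterative_fold, write_ca_pdb
from .msa import compute_weights, read_msa, trim_msa, write_fasta
from .potts import contact_scores, contacts_to_tsv, fit_plm, potts_score, save_model
from .seqstats import compute_frequencies, conservation_threshold, relative_entropy

log = logging.getLogger("coevokit")


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run."""

    workflow: str  # "design" or "fold"
    msa_path: str
    out_dir: str
    msa_format: str = "fasta"
    max_col_gap: float = 0.30
    min_query_cov: float = 0.50
    identity_threshold: float = 0.80
    pseudocount: float = 0.5
    sigma_percentile: float = 50.0
    reg_h: float = 0.01
    reg_e: float = 0.05
    design_iterations: int = 100_000
    design_trials: int = 500
    design_temperature: float = 1.0
    min_separation: int = 5
    fold_n_conformations: int = 500
    fold_elite_fraction: float = 0.20
    fold_rounds: int = 3
    fold_moves: int = 500
    torsion_path: str | None = None
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _checksum(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def run_workflow(config: RunConfig) -> dict:
    """Execute the configured workflow; returns the output manifest.

    On a stage failure the exception is re-raised with the stage name and
    every artifact written so far is renamed with a ``.partial`` suffix,
    so an interrupted run never masquerades as a complete one.
    """
    if config.workflow not in {"design", "fold"}:
        raise ValueError(f"unknown workflow {config.workflow!r}")
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    try:
        return _run_stages(config, out, artifacts, t_start)
    except Exception:
        for path in artifacts:
            if path.exists():
                path.rename(path.with_name(path.name + ".partial"))
        log.error("workflow %r failed; %d partial artifacts kept with "
                  ".partial suffix in %s", config.workflow, len(artifacts),
                  out)
        raise


def _run_stages(config: RunConfig, out: Path, artifacts: list[Path],
                t_start: float) -> dict:
    msa = read_msa(config.msa_path, format=config.msa_format)
    msa = trim_msa(msa, config.max_col_gap, config.min_query_cov)
    weights = compute_weights(msa, config.identity_threshold)
    log.info("MSA: N=%d L=%d Neff=%.1f", msa.n_sequences, msa.length,
             weights.neff)

    freq = compute_frequencies(msa, weights, config.pseudocount)
    profile = relative_entropy(freq)
    sigma = conservation_threshold(profile, "percentile",
                                   config.sigma_percentile)
    entropy_tsv = out / "conservation.tsv"
    pd.DataFrame({
        "position": np.arange(1, msa.length + 1),
        "query_residue": list(msa.alphabet.decode(msa.query)),
        "D_pos": profile.D_pos,
        "conserved": profile.D_pos > sigma,
    }).to_csv(entropy_tsv, sep="\t", index=False)
    artifacts.append(entropy_tsv)

    model = fit_plm(msa, weights, config.reg_h, config.reg_e)
    model_file = out / "potts_model.npz"
    save_model(model, model_file)
    artifacts.append(model_file)

    scores = contact_scores(model, config.min_separation)
    contacts_tsv = out / "contacts.tsv"
    contacts_to_tsv(scores, contacts_tsv)
    artifacts.append(contacts_tsv)

    if config.workflow == "design":
        scan = mutation_scan(model, msa.query)
        scan_tsv = out / "mutation_scan.tsv"
        scan.to_frame(msa.alphabet).to_csv(scan_tsv, sep="\t", index=False)
        artifacts.append(scan_tsv)

        state = metropolis_design(
            model, msa.query,
            iterations=config.design_iterations,
            temperature=config.design_temperature,
            n_trials=config.design_trials,
            seed=config.seed,
        )
        designed = out / "designed.fasta"
        wt_score = potts_score(model, msa.query)
        with open(designed, "w") as fh:
            fh.write(f">wild_type score={wt_score.E_s + wt_score.E_c:.4f}\n"
                     f"{msa.alphabet.decode(msa.query)}\n")
            fh.write(f">designed score={state.best_score:.4f}\n"
                     f"{msa.alphabet.decode(state.best_seq)}\n")
        artifacts.append(designed)
    else:
        restraints = ContactRestraints(
            [(i, j, s) for i, j, s in scores.top_pairs(msa.length) if s > 0],
            min_separation=config.min_separation,
        )
        torsion = (TorsionConstraint.from_tsv(config.torsion_path)
                   if config.torsion_path else None)
        best, history = iterative_fold(
            msa.length, restraints, torsion,
            n_conformations=config.fold_n_conformations,
            elite_fraction=config.fold_elite_fraction,
            rounds=config.fold_rounds,
            n_moves=config.fold_moves,
            seed=config.seed,
        )
        pdb = out / "best_model.pdb"
        write_ca_pdb(best, pdb)
        artifacts.append(pdb)
        rounds_tsv = out / "folding_rounds.tsv"
        pd.DataFrame([{
            "round": r.index + 1,
            "elite_restraint_energy": r.elite_energy,
            "n_restraints": r.n_restraints,
        } for r in history]).to_csv(rounds_tsv, sep="\t", index=False)
        artifacts.append(rounds_tsv)

    trimmed = out / "trimmed.fasta"
    write_fasta(msa, trimmed)
    artifacts.append(trimmed)
    config_file = out / "run_config.yaml"
    config.to_yaml(config_file)
    artifacts.append(config_file)

    manifest = {
        "workflow": config.workflow,
        "version": __version__,
        "seed": config.seed,
        "elapsed_s": round(time.time() - t_start, 3),
        "artifacts": {p.name: _checksum(p) for p in artifacts},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
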