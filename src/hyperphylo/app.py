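"""Command-line front end.

``hyperphylo --alignment data.fasta --out-dir run1`` runs the embedding
sampler end to end and leaves three artefacts in the output directory:

* ``trace.t``      — NEXUS tree trace (translate block + numbered trees)
* ``params.tsv``   — per-sample log: generation, log joint, tree length
* ``manifest.json``— config echo, seed, input digest, version, timing

The defaults (three dimensions, curvature -1, four chains) are the
general-purpose operating point; ``--euclidean`` switches the metric to the
flat code path.
"""

from __future__ import annotations

import argparse
import hashlib
import json
import sys
import time
from pathlib import Path

from . import __version__
from .evolution import PriorConfig, read_alignment
from .mcmc import MCMCConfig, run_mcmc
from .trees import read_newick, tree_length, write_nexus_trace


def build_parser() -> argparse.ArgumentParser:
    p = argparse.ArgumentParser(
        prog="hyperphylo",
        description="Bayesian phylogenetic MCMC over hyperbolic embeddings",
    )
    p.add_argument("--alignment", required=True, help="FASTA or NEXUS alignment")
    p.add_argument("--dim", type=int, default=3, help="embedding dimension (default 3)")
    p.add_argument("--curvature", type=float, default=-1.0, help="curvature kappa < 0 (default -1)")
    p.add_argument("--euclidean", action="store_true", help="use the Euclidean metric (kappa = 0)")
    p.add_argument("--generations", type=int, default=100_000)
    p.add_argument("--warmup", type=int, default=10_000)
    p.add_argument("--chains", type=int, default=4)
    p.add_argument("--swap-interval", type=int, default=1_000)
    p.add_argument("--samples", type=int, default=10_000)
    p.add_argument("--seed", type=int, default=0)
    p.add_argument(
        "--start",
        default="nj",
        help="'nj' (embed sequence distances) or 'tree:<newick path>'",
    )
    p.add_argument(
        "--prior", choices=["gamma_dirichlet", "embedding_normal"], default="gamma_dirichlet"
    )
    p.add_argument("--out-dir", default="hyperphylo_out")
    return p


def run_command(args) -> int:
    path = Path(args.alignment)
    if not path.exists():
        print(f"error: alignment file not found: {path}", file=sys.stderr)
        return 2
    try:
        Y = read_alignment(path)
    except Exception as err:
        print(f"error: could not parse alignment {path}: {err}", file=sys.stderr)
        return 2

    curvature = 0.0 if args.euclidean else args.curvature
    if not args.euclidean and curvature >= 0:
        print(
            f"error: curvature must be negative (got {curvature}); "
            "pass --euclidean for the flat metric",
            file=sys.stderr,
        )
        return 2

    start_tree = None
    start_mode = "nj"
    if args.start.startswith("tree:"):
        tree_path = Path(args.start[5:])
        if not tree_path.exists():
            print(f"error: start tree not found: {tree_path}", file=sys.stderr)
            return 2
        start_tree = read_newick(str(tree_path))
        start_mode = "given_tree"
    elif args.start != "nj":
        print(f"error: unknown start mode {args.start!r}", file=sys.stderr)
        return 2

    config = MCMCConfig(
        generations=args.generations,
        warmup=min(args.warmup, args.generations),
        n_chains=args.chains,
        swap_interval=args.swap_interval,
        n_samples=min(args.samples, max(args.generations, 1)),
        curvature=curvature,
        dimension=args.dim,
        seed=args.seed,
        start=start_mode,
        prior=PriorConfig(mode=args.prior),
    )

    t0 = time.time()
    trace = run_mcmc(Y, config, start_tree)
    elapsed = time.time() - t0

    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_nexus_trace(trace.trees, trace.generations, out / "trace.t")
    with open(out / "params.tsv", "w") as fh:
        fh.write("generation\tlog_joint\ttree_length\n")
        for g, T, lj in zip(trace.generations, trace.trees, trace.log_joints):
            fh.write(f"{g}\t{lj:.6f}\t{tree_length(T):.6f}\n")
    manifest = trace.manifest()
    manifest.update(
        {
            "alignment": str(path),
            "alignment_sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
            "start": args.start,
            "version": __version__,
            "wall_seconds": round(elapsed, 3),
        }
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    rates = ", ".join(f"{r:.3f}" for r in trace.acceptance_rates)
    print(
        f"hyperphylo: {len(trace.trees)} samples in {elapsed:.1f}s; "
        f"acceptance rates per chain: {rates}"
    )
    return 0


def main(argv=None) -> int:
    args = build_parser().parse_args(argv)
    return run_command(args)


if __name__ == "__main__":
    sys.exit(main())
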