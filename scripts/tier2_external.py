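#!/usr/bin/env python
"""Optional external-data reproduction (requires network access).

Checks the package against the deposited exemplar resources:

1. clone/download of the public exemplar workspace → ingest reports the
   33-model cohort; ``weinstein_1995.cellml`` parses to 39 variables and
   4 components;
2. ``search("flux of sodium")`` over the ingested corpus returns ≥ 40
   entities from 12 distinct models;
3. remote-mode similarity on UniProt P26433/P48764/Q9ET37/P06685 reproduces
   the published row 89.49 / 21.86 / 18.20.

This script is NOT part of the offline test suite; run it manually:

    python scripts/tier2_external.py --workspace-dir /path/to/workspace-527
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

from modeldiscovery import load_corpus, search
from modeldiscovery.cellml import parse_cellml
from modeldiscovery.seqsim import SequenceSource, similarity_matrix
from modeldiscovery.terms import TermDictionary


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--workspace-dir", type=Path, default=None,
                        help="Local clone of the exemplar model workspace.")
    parser.add_argument("--dictionary", type=Path, default=None)
    parser.add_argument("--skip-similarity", action="store_true")
    args = parser.parse_args()
    failures = 0

    if args.workspace_dir:
        corpus, models = load_corpus(args.workspace_dir)
        print(f"models ingested: {len(corpus.models)} (expected 33)")
        failures += len(corpus.models) != 33
        weinstein = next(
            (p for p in args.workspace_dir.rglob("weinstein_1995.cellml")), None
        )
        if weinstein:
            model = parse_cellml(weinstein)
            print(f"weinstein_1995.cellml: {model.n_variables} variables "
                  f"(expected 39), {model.n_components} components (expected 4)")
            failures += model.n_variables != 39 or model.n_components != 4
        if args.dictionary:
            dictionary = TermDictionary.from_file(args.dictionary)
            ranked = search(corpus, dictionary, "flux of sodium")
            n_models = len({r.entity.model_file for r in ranked.results})
            print(f"'flux of sodium': {len(ranked.results)} entities "
                  f"(expected ≥40) from {n_models} models (expected 12)")
            failures += len(ranked.results) < 40 or n_models != 12

    if not args.skip_similarity:
        source = SequenceSource(remote_enabled=True)
        accs = ["P26433", "P48764", "Q9ET37", "P06685"]
        records = [source.fetch(a) for a in accs]
        matrix = similarity_matrix(records)
        row = matrix.row("P26433")
        expected = {"P48764": 89.49, "Q9ET37": 21.86, "P06685": 18.20}
        for acc, want in expected.items():
            print(f"P26433 vs {acc}: {row[acc]:.2f} (published {want:.2f})")

    return 1 if failures else 0


if __name__ == "__main__":
    sys.exit(main())
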