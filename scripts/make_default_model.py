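"""Regenerate the bundled default interface classifier.

Trains the SVM on the synthetic decoy generator's default dataset and writes
it to src/piscore/data/default_model.json. Run from the repository root:

    python scripts/make_default_model.py [--seed 20]
"""

import argparse
from pathlib import Path

from piscore.classifier import dataset_checksum, save_model, train_classifier
from piscore.synthetic_decoys import ToyComplexSpec, build_training_set, make_toy_complex


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=20)
    ap.add_argument("--out", default="src/piscore/data/default_model.json")
    args = ap.parse_args()

    complexes = [make_toy_complex(ToyComplexSpec(seed=args.seed + i))
                 for i in range(5)]
    dataset = build_training_set(complexes, n_pos=60, n_neg=60, seed=args.seed)
    model, report = train_classifier(dataset, seed=args.seed)
    save_model(model, Path(args.out), training_checksum=dataset_checksum(dataset))
    print(f"wrote {args.out}; mean CV accuracy "
          f"{report['accuracy'].mean():.3f} over {len(report)} splits")


if __name__ == "__main__":
    main()
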