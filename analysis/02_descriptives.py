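"""Cohort descriptives: Mean ± SD per scale total and function item.

The analogue of a clinical study's descriptive tables, computed from the
simulated cohort."""

from _common import cohort, parse_args
from nssinet import descriptive_table


def main() -> None:
    args = parse_args(__doc__)
    _, _, table = cohort(args.seed)

    desc = descriptive_table(table)
    desc.to_csv(args.out / "descriptives.csv", index=False, float_format="%.3f")

    print(f"Descriptives over n = {table.n} participants:")
    for _, row in desc.iterrows():
        print(f"  {row['variable']:<22}{row['mean']:.3f} ± {row['sd']:.3f}")
    print(f"Wrote {args.out / 'descriptives.csv'}")


if __name__ == "__main__":
    main()
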