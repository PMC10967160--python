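"""Bootstrap accuracy and stability diagnostics.

Nonparametric bootstrap 95% CIs for edge weights, then a case-dropping
bootstrap for strength and bridge expected influence with the
correlation-stability (CS) coefficient.  Desk-scale replicate counts
(B = 200 / 100 instead of the production 1000) keep this script fast;
pass-level conclusions are unchanged."""

from _common import cohort, parse_args
from nssinet import bootstrap_edges, case_drop_bootstrap


def main() -> None:
    args = parse_args(__doc__)
    _, truth, table = cohort(args.seed)

    boot = bootstrap_edges(table, B=200, seed=args.seed, n_lambda=30)
    boot.summary.to_csv(args.out / "boot_edges.csv", index=False, float_format="%.3f")
    edges = boot.edges_only()
    width = (edges["ci_upper"] - edges["ci_lower"]).median()
    print(f"Edge bootstrap (B = {boot.B}): {len(edges)} edges, "
          f"median 95% CI width = {width:.3f}")

    stab = case_drop_bootstrap(
        table,
        indices=("strength", "bridge_expected_influence"),
        drop_grid=(0.1, 0.25, 0.4, 0.55, 0.75),
        B=100,
        seed=args.seed,
        communities=truth.communities,
        n_lambda=30,
    )
    stab.summary().to_csv(args.out / "stability.csv", index=False, float_format="%.3f")
    for index, cs in sorted(stab.cs().items()):
        print(f"CS coefficient ({index}): {cs}"
              + ("  [good: > 0.5]" if cs > 0.5 else
                 "  [acceptable: >= 0.25]" if cs >= 0.25 else "  [poor]"))
    print(f"Wrote boot_edges.csv and stability.csv under {args.out}")


if __name__ == "__main__":
    main()
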