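"""Training the five splice-site model families and delta-scoring a variant.

Donor sites are scored over a 9-mer (3 exonic + 6 intronic bases, GT
mandatory), acceptors over a 23-mer (20 intronic + 3 exonic, AG mandatory).
Probabilistic models report log2 odds in bits against a uniform background;
the percent score reports 100 * (t - t_min) / (t_max - t_min) over a
frequency matrix.
"""

from pexsplice import SiteWindow, delta_splice_scores, score_site, train_site_model
from pexsplice.hgvs import parse_hgvs
from pexsplice.synthetic_data import sample_training_windows

train = sample_training_windows(seed=42, site_type="acceptor", n=300)
print(f"training on {len(train)} acceptor 23-mers sampled from a canonical matrix")

models = {
    kind: train_site_model(kind, "acceptor", train)
    for kind in ("wmm", "mm1", "maxent", "mdd", "sspct")
}

strong = SiteWindow("acceptor", "TCTTTCTTTTTCCTTTCT" + "AG" + "GAA")
weak = SiteWindow("acceptor", "GAGAAAGAAAGTACGTAG".replace("G", "T")[:18] + "AG" + "GAA")
for kind, model in models.items():
    unit = "%" if kind == "sspct" else "bits"
    print(
        f"  {kind:7s} strong site {score_site(model, strong):7.2f} {unit:4s} "
        f"weak site {score_site(model, weak):7.2f} {unit}"
    )
# Stronger pyrimidine tracts score higher under every family; the percent
# score is bounded in [0, 100] while the bit scores are unbounded log odds.

# A C>A substitution converting CG to AG downstream of a pyrimidine tract:
region = "TTTTTT" + "TCTTTCTTTTTCCTTTCTTT" + "CG" + "GAAATTTTTT"
v = parse_hgvs(f"g.{1000 + 27}C>A")
report = delta_splice_scores(
    region, v, strong, [models["wmm"], models["sspct"]], seq_origin=1000
)
print("variant effect call      :", report.classification)
for kind, d in report.deltas.items():
    print(f"  {kind:7s} post {d.post_score:7.2f}  pre {d.pre_score:7.2f}  delta {d.delta:+.2f}")
# creates_new_ss: the pre-variant window has no AG, so no site existed
# before the substitution, and the post-variant site clears the calling floor.
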