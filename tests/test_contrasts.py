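import subprocess

import numpy as np
import pytest

from amaztraits.contrasts import pearson_pic, pearson_raw, pic
from amaztraits.errors import ZeroBranchError
from amaztraits.phylo_core import parse_newick, resolve_polytomies, write_newick


class TestPic:
    def test_three_taxon_hand_recursion(self, three_taxon_tree):
        # cherry (A,B): (1-2)/sqrt(2); root: weighted value 1.5 on lengthened
        # branch 1.5 against C=4 on branch 2: (1.5-4)/sqrt(3.5)
        cs = pic(three_taxon_tree, np.array([1.0, 2.0, 4.0]))
        got = sorted(cs.contrasts)
        assert got[0] == pytest.approx((1.5 - 4.0) / np.sqrt(3.5), abs=1e-12)
        assert got[1] == pytest.approx(-1.0 / np.sqrt(2.0), abs=1e-12)

    def test_constant_traits_zero_contrasts(self, three_taxon_tree):
        cs = pic(three_taxon_tree, np.full(3, 7.0))
        np.testing.assert_allclose(cs.contrasts, 0.0)

    def test_contrast_count_is_n_minus_one(self, tree_factory):
        t = tree_factory(64, seed=1)
        x = np.random.default_rng(0).normal(size=64)
        assert len(pic(t, x).contrasts) == 63

    def test_polytomy_rejected_until_resolved(self):
        t = parse_newick("(A:1,B:1,C:1);")
        with pytest.raises(ValueError, match="polytom"):
            pic(t, np.array([1.0, 2.0, 3.0]))
        assert len(pic(resolve_polytomies(t, 0), np.array([1.0, 2.0, 3.0])).contrasts) == 2

    def test_strict_zero_branch_policy_raises(self):
        t = resolve_polytomies(parse_newick("(A:0,B:0,C:1);"), seed=0)
        with pytest.raises(ZeroBranchError):
            pic(t, np.array([1.0, 2.0, 3.0]), zero_branch_policy="strict")

    def test_matches_ape_pic(self, tmp_path, tree_factory):
        """Independent cross-check against pic() in R's ape."""
        t = tree_factory(30, seed=21)
        x = np.random.default_rng(3).normal(size=30)
        cs = pic(t, x)
        (tmp_path / "t.nwk").write_text(write_newick(t))
        lines = ["genus,x"] + [f"{l},{v:.17g}" for l, v in zip(t.tip_labels, x)]
        (tmp_path / "x.csv").write_text("\n".join(lines))
        script = (
            "suppressMessages(library(ape));"
            f'tr <- read.tree("{tmp_path}/t.nwk");'
            f'd <- read.csv("{tmp_path}/x.csv");'
            "p <- pic(setNames(d$x, d$genus), tr);"
            'cat(sprintf("%.15g", sort(p)), sep="\\n")'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        r_contrasts = np.array(sorted(float(v) for v in out.stdout.split()))
        # orientation conventions differ; compare the sorted absolute values
        np.testing.assert_allclose(
            np.sort(np.abs(cs.contrasts)), np.sort(np.abs(r_contrasts)), atol=1e-8
        )


class TestContrastInvariants:
    def test_child_reorder_flips_sign_not_correlation(self, tree_factory):
        t = tree_factory(20, seed=4)
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=20), rng.normal(size=20)
        base = pearson_pic(pic(t, x), pic(t, y))
        swapped = t.copy()
        node = swapped.internal_nodes[3]
        node.children = node.children[::-1]
        swapped = type(t)(swapped.root, validate=False)
        xs = [x[t.tip_labels.index(l)] for l in swapped.tip_labels]
        ys = [y[t.tip_labels.index(l)] for l in swapped.tip_labels]
        after = pearson_pic(pic(swapped, np.array(xs)), pic(swapped, np.array(ys)))
        assert after.r == pytest.approx(base.r, abs=1e-12)

    def test_alternative_polytomy_resolutions_agree(self):
        t = parse_newick("((A:1,B:1,C:1,D:1):1,(E:2,F:1,G:1):1);")
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=7), rng.normal(size=7)
        rs = []
        for seed in (0, 1, 2):
            bt = resolve_polytomies(t, seed=seed)
            xs = np.array([x[t.tip_labels.index(l)] for l in bt.tip_labels])
            ys = np.array([y[t.tip_labels.index(l)] for l in bt.tip_labels])
            rs.append(pearson_pic(pic(bt, xs), pic(bt, ys)).r)
        assert max(rs) - min(rs) < 1e-8

    def test_unit_contrast_variance_under_bm(self, tree_factory, bm_sampler):
        t = tree_factory(100, seed=5, death_rate=0.0)
        msq = [
            np.mean(pic(t, bm_sampler(t, lam=1.0, seed=s)).contrasts ** 2)
            for s in range(40)
        ]
        assert np.mean(msq) == pytest.approx(1.0, abs=0.1)

    def test_star_tree_pic_approaches_raw_correlation(self, star_tree):
        # on a star phylogeny contrasts carry the same information as tips
        rng = np.random.default_rng(8)
        diffs = []
        star = parse_newick("(" + ",".join(f"T{i}:1.0" for i in range(40)) + ");")
        bt = resolve_polytomies(star, seed=0)
        for _ in range(30):
            x, y = rng.normal(size=40), rng.normal(size=40)
            raw = pearson_raw(x, y).r
            picr = pearson_pic(pic(bt, x), pic(bt, y)).r
            diffs.append(picr - raw)
        assert abs(np.mean(diffs)) < 0.05


class TestPearson:
    def test_identity_and_sign_flip(self):
        x = np.array([1.0, 2.0, 3.5, 5.0, 9.0])
        assert pearson_raw(x, x).r == pytest.approx(1.0)
        u = pic(parse_newick("((A:1,B:1):1,(C:1,D:1):1);"), np.array([1.0, 4.0, 2.0, 3.0]))
        assert pearson_pic(u, u).r == pytest.approx(1.0)
        neg = type(u)(-u.contrasts, u.node_ids, u.node_values)
        assert pearson_pic(u, neg).r == pytest.approx(-1.0)

    def test_raw_matches_direct_formula(self):
        x = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        y = np.array([3.0, 1.0, 5.0, 4.0, 9.0])
        res = pearson_raw(x, y)
        r_direct = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert res.r == pytest.approx(r_direct, abs=1e-12)
        t = r_direct * np.sqrt(3 / (1 - r_direct**2))
        from scipy.stats import t as tdist

        assert res.p_value == pytest.approx(2 * tdist.sf(abs(t), 3), abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_raw(np.ones(5), np.arange(5.0))

    def test_mismatched_contrast_sets_rejected(self, tree_factory):
        t1, t2 = tree_factory(10, seed=1), tree_factory(12, seed=2)
        x1 = np.random.default_rng(0).normal(size=10)
        x2 = np.random.default_rng(0).normal(size=12)
        with pytest.raises(ValueError, match="different trees"):
            pearson_pic(pic(t1, x1), pic(t2, x2))

    def test_through_origin_slope(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        u = pic(t, np.array([1.0, 4.0, 2.0, 3.0]))
        v = pic(t, np.array([2.0, 8.0, 4.0, 6.0]))
        res = pearson_pic(u, v)
        assert res.slope == pytest.approx(2.0)
        assert res.variant == "pic_through_origin"
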