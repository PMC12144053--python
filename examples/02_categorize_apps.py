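"""Look up social-media category membership and measure coder agreement.

Four categorization schemes coexist: research-coded narrow social
networking (SNS), research-coded broad social media, the Play Store's own
social genre, and the survey-defined popular platforms.  The same app can
fall under all, some, or none of them — which scheme you choose changes
every downstream usage estimate.
"""

import pandas as pd

from sm_phenotype import CATEGORIES, categorize, category_members, inter_rater_kappa, reference_key

key = reference_key()
print(f"reference key: {len(key)} apps")
for category in CATEGORIES:
    print(f"  {category:<12} {len(category_members(key, category)):>3} members")

print()
for package in ("com.snapchat.android", "com.google.android.youtube", "com.herzick.houseparty"):
    schemes = ", ".join(sorted(categorize(package, key))) or "(not social media)"
    print(f"{key.label_for(package) or package:<12} -> {schemes}")

# Coder agreement: five hypothetical coders labelling 8 apps, with one
# disagreement on YouTube's narrow-category status (a real-world sticking
# point: video platform or social network?).
ratings = pd.DataFrame(
    {
        f"coder{i}": ["sns", "sns", "broad", "broad", "none", "none", "sns", "broad"]
        for i in range(1, 6)
    }
)
ratings.loc[6, "coder5"] = "broad"  # the lone dissent
kappa = inter_rater_kappa(ratings)
print(f"\nFleiss' kappa across 5 coders, 8 apps: {kappa:.3f}")
print("(1.0 is perfect agreement; chance-level agreement gives 0)")
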