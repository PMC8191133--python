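>wnt_like_01 synthetic test sequence; astacin site embedded in body
MSTKLLVACWAGSLLNEQKKRKDPRKIMAGHELGHTLGLQHASIMHYKDETTVLRPQWND
>wnt_like_02 synthetic test sequence; no aspartate at candidate site
MSTKLLVACWAGSLLNEQKKRKNPRKIMAGQLMGNTLGLQNASIKHFKEETTVLRPQWND
>wnt_like_03 synthetic test sequence; relaxed-only site (glutamate P1')
MSTKLLVACWAGSLLNEQKKRKEPRKIMAGNALGNTAGLQNASIKHFKEETTVLRPQWND
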