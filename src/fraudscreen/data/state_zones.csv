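state,zone
AK,America/Anchorage
AK,America/Adak
AL,America/Chicago
AR,America/Chicago
AZ,America/Phoenix
AZ,America/Denver
CA,America/Los_Angeles
CO,America/Denver
CT,America/New_York
DC,America/New_York
DE,America/New_York
FL,America/New_York
FL,America/Chicago
GA,America/New_York
HI,Pacific/Honolulu
IA,America/Chicago
ID,America/Boise
ID,America/Denver
ID,America/Los_Angeles
IL,America/Chicago
IN,America/Indiana/Indianapolis
IN,America/New_York
IN,America/Chicago
KS,America/Chicago
KS,America/Denver
KY,America/New_York
KY,America/Chicago
LA,America/Chicago
MA,America/New_York
MD,America/New_York
ME,America/New_York
MI,America/Detroit
MI,America/New_York
MI,America/Menominee
MI,America/Chicago
MN,America/Chicago
MO,America/Chicago
MS,America/Chicago
MT,America/Denver
NC,America/New_York
ND,America/Chicago
ND,America/Denver
NE,America/Chicago
NE,America/Denver
NH,America/New_York
NJ,America/New_York
NM,America/Denver
NV,America/Los_Angeles
NV,America/Denver
NY,America/New_York
OH,America/New_York
OK,America/Chicago
OR,America/Los_Angeles
OR,America/Denver
PA,America/New_York
RI,America/New_York
SC,America/New_York
SD,America/Chicago
SD,America/Denver
TN,America/New_York
TN,America/Chicago
TX,America/Chicago
TX,America/Denver
UT,America/Denver
VA,America/New_York
VT,America/New_York
WA,America/Los_Angeles
WI,America/Chicago
WV,America/New_York
WY,America/Denver
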