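country_code	region
GB	Europe
DE	Europe
FR	Europe
IT	Europe
ES	Europe
NL	Europe
SE	Europe
DK	Europe
PL	Europe
CH	Europe
AT	Europe
BE	Europe
NO	Europe
FI	Europe
IE	Europe
PT	Europe
GR	Europe
CZ	Europe
HU	Europe
RO	Europe
US	NorthAmerica
CA	NorthAmerica
MX	NorthAmerica
JP	Asia
CN	Asia
IN	Asia
KR	Asia
TW	Asia
SG	Asia
TH	Asia
IL	Asia
SA	Asia
PH	Asia
AU	Oceania
NZ	Oceania
BR	SouthAmerica
AR	SouthAmerica
CO	SouthAmerica
CL	SouthAmerica
PE	SouthAmerica
VE	SouthAmerica
ZA	Africa
NG	Africa
EG	Africa
KE	Africa
MA	Africa
TN	Africa
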