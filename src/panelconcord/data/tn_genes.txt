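SHG001
SHG002
SHG003
SHG004
SHG005
SHG006
SHG007
SHG008
SHG009
SHG010
SHG011
SHG012
SHG013
SHG014
SHG015
SHG016
SHG017
SHG018
SHG019
SHG020
SHG021
SHG022
SHG023
SHG024
SHG025
SHG026
SHG027
SHG028
SHG029
SHG030
SHG031
SHG032
SHG033
SHG034
SHG035
SHG036
SHG037
SHG038
SHG039
SHG040
SHG041
SHG042
SHG043
SHG044
SHG045
SHG046
SHG047
SHG048
SHG049
SHG050
SHG051
SHG052
SHG053
SHG054
SHG055
SHG056
SHG057
SHG058
SHG059
SHG060
SHG061
SHG062
SHG063
SHG064
SHG065
SHG066
SHG067
SHG068
SHG069
SHG070
SHG071
SHG072
SHG073
SHG074
SHG075
SHG076
SHG077
SHG078
SHG079
SHG080
SHG081
SHG082
SHG083
SHG084
SHG085
SHG086
SHG087
SHG088
SHG089
SHG090
SHG091
SHG092
TNG001
TNG002
TNG003
TNG004
TNG005
TNG006
TNG007
TNG008
TNG009
TNG010
TNG011
TNG012
TNG013
TNG014
TNG015
TNG016
TNG017
TNG018
TNG019
TNG020
TNG021
TNG022
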