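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
TOG001
TOG002
TOG003
TOG004
TOG005
TOG006
TOG007
TOG008
TOG009
TOG010
TOG011
TOG012
TOG013
TOG014
TOG015
TOG016
TOG017
TOG018
TOG019
TOG020
TOG021
TOG022
TOG023
TOG024
TOG025
TOG026
TOG027
TOG028
TOG029
TOG030
TOG031
TOG032
TOG033
TOG034
TOG035
TOG036
TOG037
TOG038
TOG039
TOG040
TOG041
TOG042
TOG043
TOG044
TOG045
TOG046
TOG047
TOG048
TOG049
TOG050
TOG051
TOG052
TOG053
TOG054
TOG055
TOG056
TOG057
TOG058
TOG059
TOG060
TOG061
TOG062
TOG063
TOG064
TOG065
TOG066
TOG067
TOG068
TOG069
TOG070
TOG071
TOG072
TOG073
TOG074
TOG075
TOG076
TOG077
TOG078
TOG079
TOG080
TOG081
TOG082
TOG083
TOG084
TOG085
TOG086
TOG087
TOG088
TOG089
TOG090
TOG091
TOG092
TOG093
TOG094
TOG095
TOG096
TOG097
TOG098
TOG099
TOG100
TOG101
TOG102
TOG103
TOG104
TOG105
TOG106
TOG107
TOG108
TOG109
TOG110
TOG111
TOG112
TOG113
TOG114
TOG115
TOG116
TOG117
TOG118
TOG119
TOG120
TOG121
TOG122
TOG123
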