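Dana-Farber Cancer Institute
Memorial Sloan Kettering Cancer Center
MD Anderson Cancer Center
Mayo Clinic Cancer Center
Johns Hopkins Sidney Kimmel Comprehensive Cancer Center
Cleveland Clinic Taussig Cancer Center
Massachusetts General Hospital Cancer Center
Fred Hutchinson Cancer Center
City of Hope Comprehensive Cancer Center
Moffitt Cancer Center
Roswell Park Comprehensive Cancer Center
Fox Chase Cancer Center
Duke Cancer Institute
Stanford Cancer Institute
UCSF Helen Diller Family Comprehensive Cancer Center
UCLA Jonsson Comprehensive Cancer Center
University of Michigan Rogel Cancer Center
Ohio State University Comprehensive Cancer Center
Vanderbilt-Ingram Cancer Center
Winship Cancer Institute of Emory University
Abramson Cancer Center of the University of Pennsylvania
Robert H. Lurie Comprehensive Cancer Center
Siteman Cancer Center
Huntsman Cancer Institute
University of Colorado Cancer Center
Mays Cancer Center
UNC Lineberger Comprehensive Cancer Center
Hollings Cancer Center
Markey Cancer Center
Smilow Cancer Hospital at Yale New Haven
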